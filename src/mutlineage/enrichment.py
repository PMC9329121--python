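"""Fold-enrichment of cytosine mutations at deaminase-target motifs.

E = (Mut_motif / Con_motif) / (Mut_C / Con_C), where Mut counts qualifying
pyrimidine-strand C>T and C>G mutations (C>A at TCN is deliberately not
counted) and Con counts genome-wide availability from a context inventory.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

from .catalog import SBSRecord, classify_sbs
from .genome import (
    AmbiguousContextError,
    ContextInventory,
    OutOfRangeError,
    ReferenceGenome,
    context_at,
)

__all__ = ["EnrichmentResult", "MOTIFS", "compute_enrichment", "ytca_rtca_profile"]

MOTIFS = ("TCN", "TCA", "YTCA", "RTCA")
_Y = "CT"
_R = "AG"


@dataclass
class EnrichmentResult:
    motif: str
    mut_motif: int
    mut_c: int
    con_motif: int
    con_c: int
    e_value: float | None
    status: str  # "ok" | "insufficient data"

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


def _con_motif(inventory: ContextInventory, motif: str) -> int:
    """Availability of a motif from the inventory.

    Trinucleotide motifs come straight from tri_counts; the 4-bp YTCA/RTCA
    motifs are obtained from the pentanucleotide counts by marginalising the
    3'-most base (pentanucleotide b1 b2 C b4 b5 carries the motif at
    b1 b2 C b4).
    """
    if motif == "TCN":
        return sum(v for ctx, v in inventory.tri_counts.items() if ctx[:2] == "TC")
    if motif == "TCA":
        return inventory.tri_counts.get("TCA", 0)
    if motif in ("YTCA", "RTCA"):
        if not inventory.penta_counts:
            raise ValueError(f"motif {motif} requires a flank=2 (pentanucleotide) inventory")
        first = _Y if motif == "YTCA" else _R
        return sum(
            v
            for ctx, v in inventory.penta_counts.items()
            if ctx[0] in first and ctx[1] == "T" and ctx[2] == "C" and ctx[3] == "A"
        )
    raise ValueError(f"unknown motif {motif!r}; expected one of {MOTIFS}")


def _record_at_motif(rec: SBSRecord, genome: ReferenceGenome, motif: str) -> bool:
    flank = 1 if motif in ("TCN", "TCA") else 2
    try:
        ctx, _ = context_at(genome, rec.chrom, rec.pos, flank)
    except (OutOfRangeError, AmbiguousContextError):
        return False
    if motif == "TCN":
        return ctx[:2] == "TC"
    if motif == "TCA":
        return ctx == "TCA"
    first = _Y if motif == "YTCA" else _R
    return ctx[0] in first and ctx[1] == "T" and ctx[2] == "C" and ctx[3] == "A"


def compute_enrichment(
    records: Sequence[SBSRecord],
    inventory: ContextInventory,
    motif: str,
    genome: ReferenceGenome,
) -> EnrichmentResult:
    """Fold-enrichment of qualifying cytosine mutations at ``motif``.

    Qualifying mutations are pyrimidine-strand C>T and C>G only.  When
    either denominator is empty the result carries ``e_value=None`` with
    status "insufficient data" instead of dividing.
    """
    con_motif = _con_motif(inventory, motif)
    con_c = inventory.c_total
    mut_c = 0
    mut_motif = 0
    for rec in records:
        try:
            assign = classify_sbs(rec, genome)
        except (AmbiguousContextError, OutOfRangeError):
            continue
        if assign.class6 not in ("C>T", "C>G"):
            continue
        mut_c += 1
        if _record_at_motif(rec, genome, motif):
            mut_motif += 1
    if con_motif == 0 or con_c == 0 or mut_c == 0:
        return EnrichmentResult(motif, mut_motif, mut_c, con_motif, con_c, None, "insufficient data")
    e = (mut_motif / con_motif) / (mut_c / con_c)
    return EnrichmentResult(motif, mut_motif, mut_c, con_motif, con_c, e, "ok")


def ytca_rtca_profile(
    records: Sequence[SBSRecord],
    inventory: ContextInventory,
    genome: ReferenceGenome,
) -> dict:
    """Both tetranucleotide enrichments and their ratio.

    The ratio is E_YTCA / E_RTCA; a zero RTCA enrichment with nonzero YTCA
    enrichment is reported as ``math.inf``; undefined inputs propagate as
    None with the corresponding status.
    """
    ytca = compute_enrichment(records, inventory, "YTCA", genome)
    rtca = compute_enrichment(records, inventory, "RTCA", genome)
    ratio: float | None
    if ytca.e_value is None or rtca.e_value is None:
        ratio = None
        status = "insufficient data"
    elif rtca.e_value == 0:
        ratio = math.inf if ytca.e_value > 0 else None
        status = "ok" if ytca.e_value > 0 else "insufficient data"
    else:
        ratio = ytca.e_value / rtca.e_value
        status = "ok"
    return {"E_YTCA": ytca, "E_RTCA": rtca, "ratio": ratio, "status": status}
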