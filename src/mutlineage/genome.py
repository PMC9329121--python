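"""Reference sequences and genome-wide sequence-context availability.

Every mutation-target context is expressed on the pyrimidine strand: a
window whose central base is a purine is reverse-complemented before it is
counted or reported.  Coordinates are 1-based and fully closed throughout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
from Bio import SeqIO

__all__ = [
    "ReferenceGenome",
    "ContextInventory",
    "UnknownChromosomeError",
    "InvalidFlankError",
    "OutOfRangeError",
    "AmbiguousContextError",
    "reverse_complement",
    "context_at",
    "count_contexts",
    "ContextIndex",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# base encoding used by the vectorised kernels: A=0 C=1 G=2 T=3 N=4
_BASE_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i
_CODE_BASE = np.frombuffer(b"ACGTN", dtype=np.uint8)


class UnknownChromosomeError(KeyError):
    """Requested chromosome is not present in the genome."""


class InvalidFlankError(ValueError):
    """Flank size outside the supported {1, 2} set."""


class OutOfRangeError(ValueError):
    """Window extends past the chromosome boundary."""


class AmbiguousContextError(ValueError):
    """The requested window contains an N base."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class ReferenceGenome:
    """In-memory reference: chromosome name -> uppercase A/C/G/T/N string."""

    sequences: dict[str, str]
    _codes: dict[str, np.ndarray] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        clean = {}
        for name, seq in self.sequences.items():
            seq = seq.upper()
            if set(seq) - set("ACGTN"):
                bad = sorted(set(seq) - set("ACGTN"))
                raise ValueError(f"chromosome {name!r} contains invalid bases {bad}")
            clean[name] = seq
        self.sequences = clean

    @classmethod
    def from_fasta(cls, path: str | Path) -> "ReferenceGenome":
        records = {}
        for rec in SeqIO.parse(str(path), "fasta"):
            if rec.id in records:
                raise ValueError(f"duplicate chromosome name {rec.id!r} in {path}")
            records[rec.id] = str(rec.seq).upper()
        return cls(records)

    def to_fasta(self, path: str | Path, width: int = 80) -> None:
        with open(path, "w") as fh:
            for name, seq in self.sequences.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")

    def chrom_length(self, chrom: str) -> int:
        return len(self[chrom])

    def __getitem__(self, chrom: str) -> str:
        try:
            return self.sequences[chrom]
        except KeyError:
            raise UnknownChromosomeError(chrom) from None

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sequences

    def base_at(self, chrom: str, pos: int) -> str:
        seq = self[chrom]
        if not 1 <= pos <= len(seq):
            raise OutOfRangeError(f"{chrom}:{pos} outside 1..{len(seq)}")
        return seq[pos - 1]

    def codes(self, chrom: str) -> np.ndarray:
        """uint8 encoding (A=0 C=1 G=2 T=3 N=4) of a chromosome, cached."""
        if chrom not in self._codes:
            seq = self[chrom]
            self._codes[chrom] = _BASE_CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]
        return self._codes[chrom]


@dataclass
class ContextInventory:
    """Genome-wide availability of pyrimidine-strand mutation-target contexts.

    ``tri_counts`` holds the 32 pyrimidine-centred trinucleotides;
    ``penta_counts`` the 512 pyrimidine-centred pentanucleotides (only when
    counted with flank=2).  ``c_total`` is the number of cytosine-centred
    target positions (the Con_C denominator of motif enrichment).
    """

    tri_counts: dict[str, int] = field(default_factory=dict)
    penta_counts: dict[str, int] = field(default_factory=dict)
    c_total: int = 0
    region_spec: str = ""
    flank: int = 1
    n_skipped: int = 0

    def total(self) -> int:
        counts = self.penta_counts if self.flank == 2 else self.tri_counts
        return int(sum(counts.values()))

    def to_tsv(self, path: str | Path) -> None:
        header = {
            "region_spec": self.region_spec,
            "flank": self.flank,
            "c_total": self.c_total,
            "n_skipped": self.n_skipped,
        }
        with open(path, "w") as fh:
            fh.write("#" + json.dumps(header) + "\n")
            fh.write("context\tcount\n")
            for ctx in sorted(self.tri_counts):
                fh.write(f"{ctx}\t{self.tri_counts[ctx]}\n")
            for ctx in sorted(self.penta_counts):
                fh.write(f"{ctx}\t{self.penta_counts[ctx]}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ContextInventory":
        tri: dict[str, int] = {}
        penta: dict[str, int] = {}
        header: dict = {}
        with open(path) as fh:
            first = fh.readline()
            if first.startswith("#"):
                header = json.loads(first[1:])
                fh.readline()  # column header
            for line in fh:
                ctx, count = line.rstrip("\n").split("\t")
                if len(ctx) == 3:
                    tri[ctx] = int(count)
                else:
                    penta[ctx] = int(count)
        return cls(
            tri_counts=tri,
            penta_counts=penta,
            c_total=int(header.get("c_total", sum(v for k, v in tri.items() if k[1] == "C"))),
            region_spec=str(header.get("region_spec", "")),
            flank=int(header.get("flank", 2 if penta else 1)),
            n_skipped=int(header.get("n_skipped", 0)),
        )


def context_at(genome: ReferenceGenome, chrom: str, pos: int, flank: int) -> tuple[str, bool]:
    """Pyrimidine-strand context window centred at ``pos``.

    Returns ``(context, collapsed)`` where ``collapsed`` is True when the
    central reference base was a purine and the window was
    reverse-complemented.
    """
    if flank not in (1, 2):
        raise InvalidFlankError(f"flank must be 1 or 2, got {flank}")
    seq = genome[chrom]
    if pos - flank < 1 or pos + flank > len(seq):
        raise OutOfRangeError(f"window {chrom}:{pos}±{flank} exceeds sequence bounds")
    window = seq[pos - flank - 1 : pos + flank]
    if "N" in window:
        raise AmbiguousContextError(f"N base in window at {chrom}:{pos}")
    centre = window[flank]
    if centre in "AG":
        return reverse_complement(window), True
    return window, False


def _window_codes(codes: np.ndarray, flank: int) -> tuple[np.ndarray, np.ndarray]:
    """Pyrimidine-collapsed integer codes for every complete window.

    Returns (codes4, valid) where codes4 is the base-4 integer of the
    collapsed window (only meaningful where valid) and valid masks out
    windows containing N.
    """
    k = 2 * flank + 1
    n = codes.shape[0] - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int32), np.empty(0, dtype=bool)
    cols = [codes[i : i + n].astype(np.int32) for i in range(k)]
    valid = np.ones(n, dtype=bool)
    for col in cols:
        valid &= col < 4
    fwd = np.zeros(n, dtype=np.int32)
    for col in cols:
        fwd = fwd * 4 + col
    # reverse complement in code space: base -> 3 - base, order reversed
    rev = np.zeros(n, dtype=np.int32)
    for col in reversed(cols):
        rev = rev * 4 + (3 - col)
    centre = cols[flank]
    purine = (centre == 0) | (centre == 2)  # A or G
    out = np.where(purine, rev, fwd)
    return out, valid


def _decode(code: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append("ACGT"[code % 4])
        code //= 4
    return "".join(reversed(out))


def count_contexts(
    genome: ReferenceGenome,
    chromosomes: Iterable[str] | None = None,
    flank: int = 1,
    include_mask: Mapping[str, list[tuple[int, int]]] | None = None,
) -> ContextInventory:
    """Count pyrimidine-strand context availability over whole chromosomes.

    ``include_mask`` optionally restricts counting to 1-based closed
    intervals per chromosome (windows are kept when their central position
    falls inside an interval).  Windows touching sequence ends or containing
    N are skipped and tallied in ``n_skipped``.
    """
    if flank not in (1, 2):
        raise InvalidFlankError(f"flank must be 1 or 2, got {flank}")
    if chromosomes is None:
        chromosomes = list(genome.sequences)
    else:
        chromosomes = list(chromosomes)
        for chrom in chromosomes:
            if chrom not in genome:
                raise UnknownChromosomeError(chrom)

    k = 2 * flank + 1
    totals = np.zeros(4**k, dtype=np.int64)
    tri_totals = np.zeros(64, dtype=np.int64)
    n_skipped = 0
    for chrom in chromosomes:
        codes = genome.codes(chrom)
        wcodes, valid = _window_codes(codes, flank)
        if include_mask is not None:
            keep = np.zeros(wcodes.shape[0], dtype=bool)
            centre_pos = np.arange(1 + flank, 1 + flank + wcodes.shape[0])
            for start, end in include_mask.get(chrom, []):
                keep |= (centre_pos >= start) & (centre_pos <= end)
            valid = valid & keep
        n_skipped += int((~valid).sum()) if include_mask is None else 0
        totals += np.bincount(wcodes[valid], minlength=4**k)
        if flank == 2:
            tw, tv = _window_codes(codes, 1)
            tri_totals += np.bincount(tw[tv], minlength=64)

    inv = ContextInventory(
        region_spec=",".join(chromosomes),
        flank=flank,
        n_skipped=n_skipped,
    )
    if flank == 1:
        for code in np.flatnonzero(totals):
            inv.tri_counts[_decode(int(code), 3)] = int(totals[code])
    else:
        for code in np.flatnonzero(totals):
            inv.penta_counts[_decode(int(code), 5)] = int(totals[code])
        for code in np.flatnonzero(tri_totals):
            inv.tri_counts[_decode(int(code), 3)] = int(tri_totals[code])
    inv.c_total = int(sum(v for ctx, v in inv.tri_counts.items() if ctx[1] == "C"))
    return inv


class ContextIndex:
    """Positions of every pyrimidine-strand trinucleotide, per chromosome.

    Shared lookup used by context-preserving background simulation and by
    channel-first mutation placement.  Positions are 1-based.
    """

    def __init__(self, genome: ReferenceGenome, chromosomes: Iterable[str] | None = None):
        self.genome = genome
        self.chromosomes = list(chromosomes) if chromosomes is not None else list(genome.sequences)
        self._wcodes: dict[str, np.ndarray] = {}
        self._valid: dict[str, np.ndarray] = {}
        self._positions: dict[tuple[str, int], np.ndarray] = {}
        for chrom in self.chromosomes:
            wc, valid = _window_codes(genome.codes(chrom), 1)
            self._wcodes[chrom] = wc
            self._valid[chrom] = valid

    @staticmethod
    def context_code(context: str) -> int:
        code = 0
        for b in context:
            code = code * 4 + "ACGT".index(b)
        return code

    def positions(self, chrom: str, context: str) -> np.ndarray:
        """1-based positions on ``chrom`` whose collapsed context equals ``context``."""
        key = (chrom, self.context_code(context))
        if key not in self._positions:
            wc = self._wcodes[chrom]
            mask = (wc == key[1]) & self._valid[chrom]
            self._positions[key] = (np.flatnonzero(mask) + 2).astype(np.int64)
        return self._positions[key]
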