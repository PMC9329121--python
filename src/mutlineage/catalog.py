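"""SBS records and sequence-context channel classification.

Implements the four channel systems used throughout the pipeline:

* 6   — pyrimidine substitution classes (C>A … T>G)
* 96  — 6 classes x 16 single-base flank combinations, "A[C>A]A" naming
* 288 — 96 classes x transcription-strand category (T/U/N prefix)
* 1536 — 6 classes x 256 two-base flank combinations

Channel order is fixed (alphabetical within substitution-class blocks) so
matrices are bit-comparable across runs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .genome import (
    AmbiguousContextError,
    OutOfRangeError,
    ReferenceGenome,
    reverse_complement,
)

__all__ = [
    "SBSRecord",
    "ChannelAssignment",
    "CatalogMatrix",
    "StrandedIntervals",
    "ReferenceMismatchError",
    "CHANNELS_6",
    "CHANNELS_96",
    "CHANNELS_288",
    "CHANNELS_1536",
    "channels_for",
    "classify_sbs",
    "build_matrix",
    "collapse_matrix",
    "read_mutation_table",
    "write_mutation_table",
    "read_minimal_vcf",
]

_PYR_SUBS = ["C>A", "C>G", "C>T", "T>A", "T>C", "T>G"]
_BASES = "ACGT"

CHANNELS_6: list[str] = list(_PYR_SUBS)
CHANNELS_96: list[str] = [
    f"{l}[{sub}]{r}" for sub in _PYR_SUBS for l in _BASES for r in _BASES
]
CHANNELS_288: list[str] = [f"{s}:{ch}" for s in "TUN" for ch in CHANNELS_96]
CHANNELS_1536: list[str] = [
    f"{a}{b}[{sub}]{c}{d}"
    for sub in _PYR_SUBS
    for a, b, c, d in itertools.product(_BASES, repeat=4)
]


def channels_for(system: int) -> list[str]:
    try:
        return {6: CHANNELS_6, 96: CHANNELS_96, 288: CHANNELS_288, 1536: CHANNELS_1536}[system]
    except KeyError:
        raise ValueError(f"unknown channel system {system}; expected 6/96/288/1536") from None


class ReferenceMismatchError(ValueError):
    """Record reference base disagrees with the genome (wrong build?)."""


@dataclass
class SBSRecord:
    """One somatic single-base substitution with locus-quality fields."""

    sample_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    mut_fwd: int
    mut_rev: int
    depth: int
    ref_sample_depth: int
    ref_sample_mut: int
    asmd: float
    clpm: float
    pass_flag: bool

    def __post_init__(self) -> None:
        if self.ref not in _BASES or self.alt not in _BASES:
            raise ValueError(f"ref/alt must be A/C/G/T, got {self.ref}>{self.alt}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")
        if self.mut_fwd + self.mut_rev > self.depth:
            raise ValueError(
                f"mutant reads exceed depth at {self.chrom}:{self.pos} "
                f"({self.mut_fwd}+{self.mut_rev} > {self.depth})"
            )

    @property
    def vaf(self) -> float:
        return (self.mut_fwd + self.mut_rev) / self.depth if self.depth else 0.0

    @property
    def locus(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class ChannelAssignment:
    class6: str
    class96: str
    class288: str
    class1536: str | None
    tx_strand: str  # T / U / N


class StrandedIntervals:
    """Stranded genic intervals (1-based, closed) for 288-channel categories."""

    def __init__(self, intervals: Iterable[tuple[str, int, int, str]]):
        self._by_chrom: dict[str, list[tuple[int, int, str]]] = {}
        for chrom, start, end, strand in intervals:
            if strand not in "+-":
                raise ValueError(f"strand must be + or -, got {strand!r}")
            self._by_chrom.setdefault(chrom, []).append((start, end, strand))

    def strands_at(self, chrom: str, pos: int) -> set[str]:
        return {
            strand
            for start, end, strand in self._by_chrom.get(chrom, [])
            if start <= pos <= end
        }

    @classmethod
    def from_bed(cls, path: str | Path) -> "StrandedIntervals":
        ivals = []
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith(("#", "track")):
                    continue
                parts = line.rstrip("\n").split("\t")
                chrom, start, end = parts[0], int(parts[1]), int(parts[2])
                strand = parts[5] if len(parts) > 5 else parts[3]
                ivals.append((chrom, start + 1, end, strand))  # BED is 0-based half-open
        return cls(ivals)


def _tx_category(collapsed: bool, gene_strands: set[str]) -> str:
    """Transcription-strand category of a pyrimidine-strand mutation.

    The pyrimidine of the mutated base pair sits on '+' when the record was
    not collapsed and on '-' when it was.  If that strand is the gene's
    coding strand the mutation is 'U' (untranscribed); if it is the template
    strand it is 'T'.  Intergenic loci and loci covered by genes on both
    strands are 'N'.
    """
    if len(gene_strands) != 1:
        return "N"
    pyr_strand = "-" if collapsed else "+"
    (gene_strand,) = gene_strands
    return "U" if pyr_strand == gene_strand else "T"


def classify_sbs(
    record: SBSRecord,
    genome: ReferenceGenome,
    tx_annotation: StrandedIntervals | None = None,
) -> ChannelAssignment:
    """Assign a record to the 6/96/288/1536 channel systems.

    Raises :class:`ReferenceMismatchError` when the genome base disagrees
    with ``record.ref`` and :class:`AmbiguousContextError` when the ±1 bp
    window contains an N.  ``class1536`` is None when the ±2 bp window is
    unavailable (chromosome edge or N in the outer flank).
    """
    ref_base = genome.base_at(record.chrom, record.pos)
    if ref_base == record.ref:
        plus_ref, plus_alt = record.ref, record.alt
    elif record.ref == reverse_complement(ref_base):
        # record expressed on the minus strand: same base pair, complemented
        plus_ref, plus_alt = ref_base, reverse_complement(record.alt)
    else:
        raise ReferenceMismatchError(
            f"{record.chrom}:{record.pos} genome has {ref_base}, record claims {record.ref}"
        )
    seq = genome[record.chrom]
    if record.pos < 2 or record.pos > len(seq) - 1:
        raise OutOfRangeError(f"no ±1 bp context at {record.chrom}:{record.pos}")
    tri = seq[record.pos - 2 : record.pos + 1]
    if "N" in tri:
        raise AmbiguousContextError(f"N in ±1 bp window at {record.chrom}:{record.pos}")

    collapsed = plus_ref in "AG"
    if collapsed:
        tri = reverse_complement(tri)
        alt = reverse_complement(plus_alt)
    else:
        alt = plus_alt
    sub = f"{tri[1]}>{alt}"
    class6 = sub
    class96 = f"{tri[0]}[{sub}]{tri[2]}"

    strands = tx_annotation.strands_at(record.chrom, record.pos) if tx_annotation else set()
    tx = _tx_category(collapsed, strands)
    class288 = f"{tx}:{class96}"

    class1536 = None
    if record.pos >= 3 and record.pos <= len(seq) - 2:
        penta = seq[record.pos - 3 : record.pos + 2]
        if "N" not in penta:
            if collapsed:
                penta = reverse_complement(penta)
            class1536 = f"{penta[:2]}[{sub}]{penta[3:]}"
    return ChannelAssignment(class6, class96, class288, class1536, tx)


@dataclass
class CatalogMatrix:
    """Sample x channel mutation-count matrix for one channel system."""

    samples: list[str]
    channels: list[str]
    counts: np.ndarray  # (n_samples, n_channels) non-negative ints
    system: int
    n_excluded: int = 0
    excluded: list[SBSRecord] = field(default_factory=list, repr=False)

    def row(self, sample_id: str) -> np.ndarray:
        return self.counts[self.samples.index(sample_id)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts.T, index=self.channels, columns=self.samples)

    def to_tsv(self, path: str | Path) -> None:
        df = self.to_frame()
        df.index.name = "MutationType"
        df.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CatalogMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        system = {6: 6, 96: 96, 288: 288, 1536: 1536}[len(df.index)]
        order = channels_for(system)
        df = df.reindex(order)
        return cls(
            samples=list(df.columns),
            channels=order,
            counts=df.to_numpy().T.astype(np.int64),
            system=system,
        )


def build_matrix(
    records: Sequence[SBSRecord],
    system: int,
    genome: ReferenceGenome,
    tx_annotation: StrandedIntervals | None = None,
    samples: Sequence[str] | None = None,
) -> CatalogMatrix:
    """Classify records and tabulate per-sample channel counts.

    Records whose context is ambiguous (N in flank, edge position for the
    requested resolution) are excluded and reported via ``n_excluded``.
    """
    channels = channels_for(system)
    chan_index = {ch: j for j, ch in enumerate(channels)}
    if samples is None:
        seen: dict[str, None] = {}
        for rec in records:
            seen.setdefault(rec.sample_id, None)
        samples = list(seen)
    samples = list(samples)
    sample_index = {s: i for i, s in enumerate(samples)}
    counts = np.zeros((len(samples), len(channels)), dtype=np.int64)
    excluded: list[SBSRecord] = []
    for rec in records:
        try:
            assign = classify_sbs(rec, genome, tx_annotation)
        except (AmbiguousContextError, OutOfRangeError):
            excluded.append(rec)
            continue
        key = {
            6: assign.class6,
            96: assign.class96,
            288: assign.class288,
            1536: assign.class1536,
        }[system]
        if key is None:
            excluded.append(rec)
            continue
        counts[sample_index[rec.sample_id], chan_index[key]] += 1
    return CatalogMatrix(samples, channels, counts, system, len(excluded), excluded)


def _parent_channel(channel: str, from_system: int, to_system: int) -> str:
    if from_system == 1536:
        ch96 = channel[1:-1]  # strip outer flanks: "AA[C>A]TT" -> "A[C>A]T"
    elif from_system == 288:
        ch96 = channel.split(":", 1)[1]
    elif from_system == 96:
        ch96 = channel
    else:
        raise ValueError(f"cannot collapse from system {from_system}")
    if to_system == 96:
        return ch96
    if to_system == 6:
        return ch96[2:5]
    raise ValueError(f"cannot collapse to system {to_system}")


def collapse_matrix(matrix: CatalogMatrix, to_system: int) -> CatalogMatrix:
    """Sum channels of a finer system down to a coarser one (1536/288/96 -> 96/6)."""
    channels = channels_for(to_system)
    chan_index = {ch: j for j, ch in enumerate(channels)}
    counts = np.zeros((len(matrix.samples), len(channels)), dtype=np.int64)
    for j, ch in enumerate(matrix.channels):
        counts[:, chan_index[_parent_channel(ch, matrix.system, to_system)]] += matrix.counts[:, j]
    return CatalogMatrix(list(matrix.samples), channels, counts, to_system, matrix.n_excluded)


# ---------------------------------------------------------------------------
# tabular IO

_TABLE_COLUMNS = [
    "sample_id",
    "chrom",
    "pos",
    "ref",
    "alt",
    "mut_fwd",
    "mut_rev",
    "depth",
    "ref_sample_depth",
    "ref_sample_mut",
    "asmd",
    "clpm",
    "pass_flag",
]


def write_mutation_table(records: Sequence[SBSRecord], path: str | Path) -> None:
    rows = [
        {col: getattr(rec, col) for col in _TABLE_COLUMNS}
        for rec in records
    ]
    df = pd.DataFrame(rows, columns=_TABLE_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_mutation_table(path: str | Path) -> list[SBSRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "sample_id": str})
    missing = set(_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"mutation table {path} missing columns: {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        records.append(
            SBSRecord(
                sample_id=str(row.sample_id),
                chrom=str(row.chrom),
                pos=int(row.pos),
                ref=str(row.ref),
                alt=str(row.alt),
                mut_fwd=int(row.mut_fwd),
                mut_rev=int(row.mut_rev),
                depth=int(row.depth),
                ref_sample_depth=int(row.ref_sample_depth),
                ref_sample_mut=int(row.ref_sample_mut),
                asmd=float(row.asmd),
                clpm=float(row.clpm),
                pass_flag=bool(row.pass_flag),
            )
        )
    return records


def read_minimal_vcf(path: str | Path, sample_id: str | None = None) -> list[SBSRecord]:
    """Read SBSs from a minimal single-sample VCF.

    Expected keys: INFO ``ASMD``, ``CLPM``, ``RDP`` (reference-sample depth)
    and ``RMUT`` (reference-sample mutant reads); FORMAT ``DP`` (depth),
    ``MF``/``MR`` (mutant reads forward/reverse).  FILTER ``PASS`` maps to
    ``pass_flag``.  Multi-allelic and non-SNV rows are skipped.
    """
    records: list[SBSRecord] = []
    with open(path) as fh:
        header_sample = None
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("##") or not line:
                continue
            if line.startswith("#CHROM"):
                cols = line.split("\t")
                if len(cols) > 9:
                    header_sample = cols[9]
                continue
            fields = line.split("\t")
            chrom, pos, _id, ref, alt, _qual, filt, info = fields[:8]
            if len(ref) != 1 or len(alt) != 1 or "," in alt or ref not in "ACGT" or alt not in "ACGT":
                continue
            info_d = dict(kv.split("=", 1) for kv in info.split(";") if "=" in kv)
            fmt = dict(zip(fields[8].split(":"), fields[9].split(":"))) if len(fields) > 9 else {}
            records.append(
                SBSRecord(
                    sample_id=sample_id or header_sample or "sample",
                    chrom=chrom,
                    pos=int(pos),
                    ref=ref,
                    alt=alt,
                    mut_fwd=int(fmt.get("MF", 0)),
                    mut_rev=int(fmt.get("MR", 0)),
                    depth=int(fmt.get("DP", 0)),
                    ref_sample_depth=int(info_d.get("RDP", 0)),
                    ref_sample_mut=int(info_d.get("RMUT", 0)),
                    asmd=float(info_d.get("ASMD", "nan")),
                    clpm=float(info_d.get("CLPM", "nan")),
                    pass_flag=(filt == "PASS"),
                )
            )
    return records
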