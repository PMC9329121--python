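"""Two-step identification of de novo mutations in clone lineages.

Step one removes low-quality loci with four post-hoc filters applied to
panel-of-normals PASS calls; step two genotypes the surviving loci across
all clones of the cell line and removes mutations present in the reference
sample or shared across most other parental lineages.  Step-two removals
accumulate into a bulk-proxy catalogue.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .catalog import SBSRecord

__all__ = [
    "Clone",
    "CloneManifest",
    "GenotypeTable",
    "FilterReport",
    "FilterThresholds",
    "MissingQualityFieldError",
    "UnknownCloneError",
    "apply_locus_filters",
    "genotype_presence",
    "derive_de_novo",
    "flag_shared_daughters",
    "vaf_clonality_diagnostic",
]

FILTER_NAMES = ["f0_nonpass", "f1_asmd", "f2_clpm", "f3_refcov", "f4_direction"]


class MissingQualityFieldError(ValueError):
    pass


class UnknownCloneError(KeyError):
    pass


@dataclass
class Clone:
    clone_id: str
    role: str  # parent | daughter
    lineage_id: str
    parent_id: str | None = None
    reference_id: str | None = None
    days_propagated: float | None = None
    genotype: str | None = None  # optional experimental-group label

    def __post_init__(self) -> None:
        if self.role not in ("parent", "daughter"):
            raise ValueError(f"role must be parent/daughter, got {self.role!r}")


@dataclass
class CloneManifest:
    cell_line: str
    clones: list[Clone]

    def __post_init__(self) -> None:
        ids = [c.clone_id for c in self.clones]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate clone_id in manifest")
        parents = {c.clone_id for c in self.clones if c.role == "parent"}
        for c in self.clones:
            if c.role == "daughter" and c.parent_id not in parents:
                raise ValueError(
                    f"daughter {c.clone_id} names unknown parent {c.parent_id!r}"
                )

    def clone(self, clone_id: str) -> Clone:
        for c in self.clones:
            if c.clone_id == clone_id:
                return c
        raise UnknownCloneError(clone_id)

    def daughters_of(self, parent_id: str) -> list[Clone]:
        return [c for c in self.clones if c.role == "daughter" and c.parent_id == parent_id]

    def other_lineage_clones(self, clone_id: str) -> list[Clone]:
        """All clones whose lineage differs from the focal clone's lineage."""
        focal = self.clone(clone_id)
        return [c for c in self.clones if c.lineage_id != focal.lineage_id]

    def to_yaml(self, path: str | Path) -> None:
        data = {
            "cell_line": self.cell_line,
            "clones": [
                {k: v for k, v in vars(c).items() if v is not None}
                for c in self.clones
            ],
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CloneManifest":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(
            cell_line=data["cell_line"],
            clones=[Clone(**c) for c in data["clones"]],
        )


@dataclass
class GenotypeTable:
    """Mutant/total read counts per locus per clone (re-genotyping counts)."""

    loci: list[tuple[str, int, str, str]]  # (chrom, pos, ref, alt)
    clones: list[str]
    mut_reads: np.ndarray  # (n_loci, n_clones)
    total_reads: np.ndarray

    def __post_init__(self) -> None:
        self.mut_reads = np.asarray(self.mut_reads, dtype=np.int64)
        self.total_reads = np.asarray(self.total_reads, dtype=np.int64)
        if (self.mut_reads > self.total_reads).any() or (self.mut_reads < 0).any():
            raise ValueError("genotype table requires 0 <= mut_reads <= total_reads")

    def locus_index(self) -> dict[tuple[str, int, str, str], int]:
        return {locus: i for i, locus in enumerate(self.loci)}

    def to_tsv(self, path: str | Path) -> None:
        rows = []
        for i, (chrom, pos, ref, alt) in enumerate(self.loci):
            for j, clone in enumerate(self.clones):
                rows.append(
                    (chrom, pos, ref, alt, clone, self.mut_reads[i, j], self.total_reads[i, j])
                )
        pd.DataFrame(
            rows,
            columns=["chrom", "pos", "ref", "alt", "clone", "mut_reads", "total_reads"],
        ).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GenotypeTable":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "clone": str})
        loci = list(
            dict.fromkeys(zip(df["chrom"], df["pos"].astype(int), df["ref"], df["alt"]))
        )
        clones = list(dict.fromkeys(df["clone"]))
        li = {l: i for i, l in enumerate(loci)}
        ci = {c: j for j, c in enumerate(clones)}
        mut = np.zeros((len(loci), len(clones)), dtype=np.int64)
        tot = np.zeros((len(loci), len(clones)), dtype=np.int64)
        for row in df.itertuples(index=False):
            i = li[(row.chrom, int(row.pos), row.ref, row.alt)]
            j = ci[row.clone]
            mut[i, j] = int(row.mut_reads)
            tot[i, j] = int(row.total_reads)
        return cls(loci, clones, mut, tot)


@dataclass
class FilterThresholds:
    asmd_max_removed: float = 130.0  # remove when asmd <= this
    refcov_min: int = 16  # remove when reference-sample depth < this


@dataclass
class FilterReport:
    removed: dict[str, int] = field(default_factory=dict)
    retained: int = 0
    bulk_proxy: int = 0
    shared_daughter_flags: dict[str, float] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(vars(self), fh, indent=2)


def _failing_filter(rec: SBSRecord, thresholds: FilterThresholds) -> str | None:
    """First locus filter a record fails, or None when it passes all."""
    for fieldname in ("asmd", "clpm"):
        if np.isnan(getattr(rec, fieldname)):
            raise MissingQualityFieldError(
                f"record {rec.chrom}:{rec.pos} missing {fieldname}"
            )
    if not rec.pass_flag:
        return "f0_nonpass"
    if rec.asmd <= thresholds.asmd_max_removed:
        return "f1_asmd"
    if rec.clpm > 0:
        return "f2_clpm"
    if rec.ref_sample_depth < thresholds.refcov_min:
        return "f3_refcov"
    if rec.mut_fwd < 1 or rec.mut_rev < 1:
        return "f4_direction"
    return None


def apply_locus_filters(
    records: Sequence[SBSRecord],
    thresholds: FilterThresholds | None = None,
) -> tuple[list[SBSRecord], dict[str, list[SBSRecord]]]:
    """Step-one locus filters.

    Non-PASS records are removed first; then the four quality filters in
    order (ASMD <= 130; CLPM > 0; reference-sample coverage < 16 reads;
    missing read-direction support).  Each removed record is attributed to
    the first filter that rejects it.
    """
    thresholds = thresholds or FilterThresholds()
    retained: list[SBSRecord] = []
    removed: dict[str, list[SBSRecord]] = {name: [] for name in FILTER_NAMES}
    for rec in records:
        name = _failing_filter(rec, thresholds)
        if name is None:
            retained.append(rec)
        else:
            removed[name].append(rec)
    return retained, removed


def genotype_presence(genotypes: GenotypeTable, min_mut_reads: int = 1) -> np.ndarray:
    """Boolean loci x clones matrix: present iff mut_reads >= min_mut_reads."""
    return genotypes.mut_reads >= min_mut_reads


def derive_de_novo(
    clone_id: str,
    retained: Sequence[SBSRecord],
    genotypes: GenotypeTable,
    presence: np.ndarray,
    manifest: CloneManifest,
) -> tuple[list[SBSRecord], dict[str, list[SBSRecord]]]:
    """Step-two lineage filters for one clone.

    Removes records present in any read of the clone's reference sample
    (f5) or present in strictly more than 50% of clones from other parental
    lineages (f6).  Removed records form this clone's contribution to the
    bulk-proxy catalogue.
    """
    clone = manifest.clone(clone_id)
    locus_index = genotypes.locus_index()
    clone_cols = {c: j for j, c in enumerate(genotypes.clones)}

    ref_col = clone_cols.get(clone.reference_id)
    other = [
        c.clone_id
        for c in manifest.other_lineage_clones(clone_id)
        if c.clone_id in clone_cols
    ]
    other_cols = [clone_cols[c] for c in other]

    de_novo: list[SBSRecord] = []
    removed: dict[str, list[SBSRecord]] = {"f5_ref_reads": [], "f6_other_lineages": []}
    for rec in retained:
        i = locus_index.get(rec.locus)
        ref_present = False
        if rec.ref_sample_mut > 0:
            ref_present = True
        elif i is not None and ref_col is not None and presence[i, ref_col]:
            ref_present = True
        if ref_present:
            removed["f5_ref_reads"].append(rec)
            continue
        if i is not None and other_cols:
            frac = presence[i, other_cols].mean()
            if frac > 0.5:
                removed["f6_other_lineages"].append(rec)
                continue
        de_novo.append(rec)
    return de_novo, removed


def flag_shared_daughters(
    catalogs: Mapping[str, Sequence[SBSRecord]],
    threshold: float = 0.30,
) -> tuple[set[str], pd.DataFrame]:
    """Flag sibling daughters sharing a high fraction of de novo mutations.

    The shared fraction for daughter d against sibling e is
    |catalog(d) ∩ catalog(e)| / |catalog(d)| — asymmetric by design so a
    small catalogue nested inside a large sibling is still flagged.
    Daughters with any pairwise fraction > ``threshold`` are flagged for
    exclusion from burden statistics.
    """
    names = list(catalogs)
    loci = {d: {rec.locus for rec in recs} for d, recs in catalogs.items()}
    frac = pd.DataFrame(0.0, index=names, columns=names)
    flags: set[str] = set()
    for d in names:
        for e in names:
            if d == e or not loci[d]:
                continue
            f = len(loci[d] & loci[e]) / len(loci[d])
            frac.loc[d, e] = f
            if f > threshold:
                flags.add(d)
    return flags, frac


def vaf_clonality_diagnostic(
    records: Sequence[SBSRecord],
    bin_width: float = 0.02,
    smoothing_bandwidth: float = 0.05,
    min_records: int = 50,
    rel_height: float = 0.10,
) -> dict:
    """Detect multimodality of the VAF distribution of one clone.

    A Gaussian-kernel density (fixed bandwidth on the VAF axis) is evaluated
    on a fine grid; modes are local maxima above ``rel_height`` of the
    global maximum.  One mode labels the clone clonal; more suggest
    subclonality.  Fewer than ``min_records`` records yields an
    "underpowered" label instead of a call.
    """
    vafs = np.array([rec.vaf for rec in records], dtype=float)
    edges = np.arange(0.0, 1.0 + bin_width, bin_width)
    hist, _ = np.histogram(vafs, bins=edges)
    result = {
        "n": int(vafs.size),
        "histogram": hist.tolist(),
        "bin_edges": edges.tolist(),
    }
    if vafs.size < min_records:
        result.update({"label": "underpowered", "mode_count": None, "mode_positions": []})
        return result
    grid = np.linspace(0.0, 1.0, 401)
    # fixed-bandwidth Gaussian KDE; scipy's gaussian_kde scales bandwidth by
    # the sample std which defeats a fixed smoothing contract
    z = (grid[:, None] - vafs[None, :]) / smoothing_bandwidth
    density = np.exp(-0.5 * z**2).sum(axis=1)
    peak = density.max()
    modes = []
    for i in range(1, grid.size - 1):
        if density[i] >= density[i - 1] and density[i] > density[i + 1]:
            if density[i] >= rel_height * peak:
                modes.append(float(grid[i]))
    label = "clonal" if len(modes) == 1 else "possible subclonality"
    result.update({"label": label, "mode_count": len(modes), "mode_positions": modes})
    return result
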