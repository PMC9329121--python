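"""Fully synthetic clone-lineage studies with per-mutation ground truth.

Generates a random reference genome, a parent/daughter clone manifest, and
per-clone mutation call tables whose statistical structure matches what the
pipeline assumes: clonal VAFs near 0.5 with binomial read sampling,
signature-mixture spectra sampled channel-first (so the generating mixture
is exactly the sampling distribution), episodic per-daughter burden bursts,
strand-coordinated clusters with short IMDs, shared germline/parental
variants removable by the lineage filters, and an optional artifact
fraction for the locus filters to remove.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .catalog import CHANNELS_96, SBSRecord
from .genome import ContextIndex, ReferenceGenome, reverse_complement
from .lineage import Clone, CloneManifest, GenotypeTable
from .signatures import ReferenceSignatureSet

__all__ = [
    "SimulationConfig",
    "TruthTables",
    "simulate_genome",
    "simulate_study",
    "synthetic_signature_set",
    "apobec_like_signature_set",
]

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass
class SimulationConfig:
    chromosomes: dict[str, int] = field(default_factory=lambda: {"chr1": 2_000_000})
    base_composition: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)

    n_parents: int = 2
    daughters_per_parent: int = 2
    days: float = 100.0
    cell_line: str = "SYN-1"
    # genotype label per parent, cycled when shorter than n_parents
    parent_genotypes: list[str] = field(default_factory=lambda: ["WT"])
    # genotype -> {signature name -> mean de novo mutation count per daughter}
    signature_activities: dict[str, dict[str, float]] = field(
        default_factory=lambda: {"WT": {"FLAT-1": 1000.0}}
    )
    burst_signatures: list[str] = field(default_factory=list)
    burst_sigma: float = 1.0  # lognormal sigma of the episodic multiplier

    n_germline: int = 100
    n_parent_private: int = 50
    n_bulk_shared: int = 0  # loci shared across other lineages, absent from references

    n_kataegis: int = 0
    n_omikli: int = 0
    kataegis_members: tuple[int, int] = (4, 8)
    omikli_members: tuple[int, int] = (2, 3)
    cluster_imd_range: tuple[int, int] = (2, 8)
    apobec_target_prob: float = 0.9
    cluster_vaf: float = 0.5

    mean_depth: float = 30.0
    clonal_vaf: float = 0.5
    subclone_fraction: float = 0.0  # de novo fraction drawn at subclone VAF
    subclone_vaf: float = 0.25

    artifact_fraction: float = 0.0
    shared_subclone: bool = False
    shared_subclone_count: int = 200

    def __post_init__(self) -> None:
        for p in (*self.base_composition, self.apobec_target_prob, self.artifact_fraction,
                  self.subclone_fraction, self.clonal_vaf, self.subclone_vaf, self.cluster_vaf):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        if any(length <= 0 for length in self.chromosomes.values()):
            raise ValueError("chromosome lengths must be positive")

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        for key in ("base_composition", "kataegis_members", "omikli_members", "cluster_imd_range"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        return cls(**data)


@dataclass
class TruthTables:
    """Per-mutation provenance: one row per emitted record."""

    frame: pd.DataFrame  # clone, chrom, pos, ref, alt, origin, signature, cluster_id, cluster_class

    def de_novo_loci(self, clone_id: str) -> set[tuple[str, int, str, str]]:
        df = self.frame
        sel = df[(df["clone"] == clone_id) & df["origin"].isin(["de_novo", "cluster"])]
        return set(zip(sel["chrom"], sel["pos"], sel["ref"], sel["alt"]))

    def to_tsv(self, path: str | Path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)


def simulate_genome(config: SimulationConfig, seed: int = 0) -> ReferenceGenome:
    """I.i.d. base sampling at the configured composition; deterministic from seed."""
    rng = np.random.default_rng(seed)
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    p = np.asarray(config.base_composition, dtype=float)
    p = p / p.sum()
    sequences = {}
    for name, length in config.chromosomes.items():
        draw = rng.choice(4, size=length, p=p)
        sequences[name] = bases[draw].tobytes().decode()
    return ReferenceGenome(sequences)


def synthetic_signature_set(
    n_signatures: int,
    seed: int = 0,
    include_flat: bool = True,
    n_peaks: int = 3,
    peak_mass: float = 0.95,
) -> ReferenceSignatureSet:
    """Random well-separated peaked signatures (plus one flat profile).

    Peak channels are drawn from a shared permutation so that (up to 32
    signatures of 3 peaks) no two peaked signatures share a peak channel,
    making refitting well-posed; the flat profile reproduces the hard case.
    """
    rng = np.random.default_rng(seed)
    perm = rng.permutation(96)
    cols = []
    names = []
    n_peaked = n_signatures - (1 if include_flat else 0)
    for i in range(n_peaked):
        start = (i * n_peaks) % 96
        peaks = perm[start : start + n_peaks]
        if peaks.size < n_peaks:  # wrap for very large sets
            peaks = np.concatenate([peaks, perm[: n_peaks - peaks.size]])
        col = rng.uniform(0.0005, 0.002, size=96)
        w = rng.uniform(0.5, 1.0, size=n_peaks)
        col[peaks] = w / w.sum() * peak_mass / (1 - peak_mass) * col.sum()
        cols.append(col / col.sum())
        names.append(f"SYN-{i + 1}")
    if include_flat:
        col = rng.uniform(0.8, 1.2, size=96)
        cols.append(col / col.sum())
        names.append("FLAT-1")
    return ReferenceSignatureSet(names, np.column_stack(cols))


def apobec_like_signature_set(seed: int = 0) -> ReferenceSignatureSet:
    """Three-signature set: deaminase-like C>T and C>G at TCN, plus flat."""
    idx = {ch: i for i, ch in enumerate(CHANNELS_96)}
    rng = np.random.default_rng(seed)
    ct = np.full(96, 1e-4)
    cg = np.full(96, 1e-4)
    for n3 in "ACGT":
        ct[idx[f"T[C>T]{n3}"]] = 1.0
        cg[idx[f"T[C>G]{n3}"]] = 1.0
    flat = rng.uniform(0.8, 1.2, size=96)
    cols = [ct / ct.sum(), cg / cg.sum(), flat / flat.sum()]
    return ReferenceSignatureSet(["APO-CT", "APO-CG", "FLAT-1"], np.column_stack(cols))


# ---------------------------------------------------------------------------
# study generation

_CHANNEL_CONTEXT = {ch: (ch[0] + ch[2] + ch[6], ch[4]) for ch in CHANNELS_96}


class _Placer:
    """Channel-first placement of mutations at matching genomic sites."""

    def __init__(self, genome: ReferenceGenome, index: ContextIndex):
        self.genome = genome
        self.index = index
        self.used: set[tuple[str, int]] = set()
        self.chroms = list(genome.sequences)
        self._avail_cache: dict[str, np.ndarray] = {}

    def _availability(self, context: str) -> np.ndarray:
        if context not in self._avail_cache:
            self._avail_cache[context] = np.array(
                [self.index.positions(c, context).size for c in self.chroms], dtype=float
            )
        return self._avail_cache[context]

    def place(self, rng: np.random.Generator, channel: str) -> tuple[str, int, str, str] | None:
        """One unused site matching the channel's context; ref/alt on the + strand."""
        context, pyr_alt = _CHANNEL_CONTEXT[channel]
        avail = self._availability(context)
        if avail.sum() == 0:
            return None
        for _ in range(50):
            ci = rng.choice(len(self.chroms), p=avail / avail.sum())
            chrom = self.chroms[ci]
            pop = self.index.positions(chrom, context)
            pos = int(pop[rng.integers(pop.size)])
            if (chrom, pos) in self.used:
                continue
            self.used.add((chrom, pos))
            ref = self.genome.base_at(chrom, pos)
            alt = pyr_alt if ref in "CT" else _COMPLEMENT[pyr_alt]
            return chrom, pos, ref, alt
        return None

    def place_random(self, rng: np.random.Generator) -> tuple[str, int, str, str]:
        """One unused non-N site anywhere, with a random alt."""
        lengths = np.array([len(self.genome[c]) for c in self.chroms], dtype=float)
        while True:
            ci = rng.choice(len(self.chroms), p=lengths / lengths.sum())
            chrom = self.chroms[ci]
            pos = int(rng.integers(2, len(self.genome[chrom])))
            if (chrom, pos) in self.used:
                continue
            ref = self.genome.base_at(chrom, pos)
            if ref == "N":
                continue
            self.used.add((chrom, pos))
            alt = rng.choice([b for b in "ACGT" if b != ref])
            return chrom, pos, ref, str(alt)


def _clean_reads(rng: np.random.Generator, mean_depth: float, vaf: float) -> dict:
    """Read counts guaranteed to pass every locus filter."""
    depth = max(10, int(rng.poisson(mean_depth)))
    mut = int(rng.binomial(depth, vaf))
    mut = min(max(mut, 2), depth)
    fwd = 1 + int(rng.binomial(mut - 2, 0.5)) if mut > 2 else 1
    return {
        "mut_fwd": fwd,
        "mut_rev": mut - fwd,
        "depth": depth,
        "ref_sample_depth": max(16, int(rng.poisson(mean_depth))),
        "asmd": float(rng.uniform(140.0, 250.0)),
        "clpm": 0.0,
        "pass_flag": True,
    }


def _make_record(
    rng: np.random.Generator,
    sample_id: str,
    locus: tuple[str, int, str, str],
    cfg: SimulationConfig,
    vaf: float,
    ref_sample_mut: int = 0,
) -> SBSRecord:
    chrom, pos, ref, alt = locus
    fields = _clean_reads(rng, cfg.mean_depth, vaf)
    if ref_sample_mut > 0:
        fields["ref_sample_mut"] = min(ref_sample_mut, fields["ref_sample_depth"])
    else:
        fields["ref_sample_mut"] = 0
    return SBSRecord(sample_id=sample_id, chrom=chrom, pos=pos, ref=ref, alt=alt, **fields)


def _corrupt(rng: np.random.Generator, rec: SBSRecord, defect: str) -> SBSRecord:
    if defect == "nonpass":
        rec.pass_flag = False
    elif defect == "asmd":
        rec.asmd = float(rng.uniform(50.0, 130.0))
    elif defect == "clpm":
        rec.clpm = float(rng.uniform(0.1, 3.0))
    elif defect == "refcov":
        rec.ref_sample_depth = int(rng.integers(0, 16))
        rec.ref_sample_mut = min(rec.ref_sample_mut, rec.ref_sample_depth)
    elif defect == "direction":
        mut = rec.mut_fwd + rec.mut_rev
        rec.mut_fwd, rec.mut_rev = mut, 0
    return rec


_ARTIFACT_DEFECTS = ["nonpass", "asmd", "clpm", "refcov", "direction"]


def _inject_cluster(
    rng: np.random.Generator,
    placer: _Placer,
    genome: ReferenceGenome,
    index: ContextIndex,
    n_members: int,
    cfg: SimulationConfig,
) -> list[tuple[str, int, str, str]] | None:
    """A strand-coordinated run with configured IMDs; None when placement fails."""
    lo, hi = cfg.cluster_imd_range
    chroms = list(genome.sequences)
    apobec_cache: dict[str, np.ndarray] = {}
    for _ in range(50):
        chrom = chroms[rng.integers(len(chroms))]
        length = len(genome[chrom])
        span_budget = n_members * (hi + 2)
        if length < span_budget + 6:
            continue
        if chrom not in apobec_cache:
            parts = [index.positions(chrom, "TC" + b) for b in "ACGT"]
            apobec_cache[chrom] = np.sort(np.concatenate(parts))
        apobec_sites = apobec_cache[chrom]
        anchor = int(rng.integers(3, length - span_budget))
        members: list[tuple[str, int, str, str]] = []
        pos = anchor
        ok = True
        for i in range(n_members):
            want_apobec = rng.random() < cfg.apobec_target_prob
            site = None
            if want_apobec:
                w_lo = pos if i == 0 else pos + lo
                w_hi = pos + hi if i > 0 else pos + hi + 20
                a, b = np.searchsorted(apobec_sites, [w_lo, w_hi + 1])
                window = [
                    int(s) for s in apobec_sites[a:b] if (chrom, int(s)) not in placer.used
                ]
                if window:
                    site = window[int(rng.integers(len(window)))]
                    ref = genome.base_at(chrom, site)
                    pyr_alt = "T" if rng.random() < 0.5 else "G"  # C>T / C>G
                    alt = pyr_alt if ref == "C" else _COMPLEMENT[pyr_alt]
            if site is None:  # non-deaminase member (or no motif site in window)
                site = pos if i == 0 else pos + int(rng.integers(lo, hi + 1))
                ref = genome.base_at(chrom, site)
                if ref == "N" or (chrom, site) in placer.used:
                    ok = False
                    break
                alt = str(rng.choice([b for b in "ACGT" if b != ref]))
            members.append((chrom, site, ref, alt))
            pos = site
        if ok and len(members) == n_members:
            for m in members:
                placer.used.add((m[0], m[1]))
            return members
    return None


def simulate_study(
    config: SimulationConfig,
    genome: ReferenceGenome,
    refs: ReferenceSignatureSet,
    seed: int = 0,
) -> tuple[dict[str, list[SBSRecord]], CloneManifest, GenotypeTable, TruthTables]:
    """Generate per-clone call tables, manifest, genotyping counts and truth.

    Raises ``RuntimeError`` when a requested cluster cannot be placed after
    bounded retries (genome too small for the configured IMDs).
    """
    rng = np.random.default_rng(seed)
    index = ContextIndex(genome)
    placer = _Placer(genome, index)

    # manifest ------------------------------------------------------------
    clones: list[Clone] = []
    genotype_of: dict[str, str] = {}
    for i in range(config.n_parents):
        pid = f"P{i + 1}"
        gt = config.parent_genotypes[i % len(config.parent_genotypes)]
        clones.append(Clone(pid, "parent", f"L{i + 1}", None, "normal", config.days, gt))
        genotype_of[pid] = gt
        for j in range(config.daughters_per_parent):
            did = f"D{i + 1}.{j + 1}"
            clones.append(Clone(did, "daughter", f"L{i + 1}", pid, pid, config.days, gt))
            genotype_of[did] = gt
    manifest = CloneManifest(config.cell_line, clones)
    daughters = [c for c in clones if c.role == "daughter"]
    parents = [c for c in clones if c.role == "parent"]

    records: dict[str, list[SBSRecord]] = {c.clone_id: [] for c in clones}
    truth_rows: list[dict] = []
    # genotype-table presence: locus -> set of clone_ids carrying it
    carriers: dict[tuple[str, int, str, str], set[str]] = defaultdict(set)

    def emit(clone_id: str, locus: tuple, origin: str, vaf: float, ref_mut: int = 0,
             signature: str | None = None, cluster_id: str | None = None,
             cluster_class: str | None = None, defect: str | None = None) -> None:
        rec = _make_record(rng, clone_id, locus, config, vaf, ref_mut)
        if defect is not None:
            rec = _corrupt(rng, rec, defect)
        records[clone_id].append(rec)
        truth_rows.append(
            {
                "clone": clone_id,
                "chrom": locus[0],
                "pos": locus[1],
                "ref": locus[2],
                "alt": locus[3],
                "origin": origin,
                "signature": signature,
                "cluster_id": cluster_id,
                "cluster_class": cluster_class,
            }
        )

    # germline: in every clone -------------------------------------------
    for _ in range(config.n_germline):
        locus = placer.place_random(rng)
        carriers[locus] = {c.clone_id for c in clones}
        for c in clones:
            emit(c.clone_id, locus, "germline", config.clonal_vaf, ref_mut=5)

    # parent-private: parent + its daughters ------------------------------
    for parent in parents:
        kids = [d.clone_id for d in manifest.daughters_of(parent.clone_id)]
        for _ in range(config.n_parent_private):
            locus = placer.place_random(rng)
            carriers[locus] = {parent.clone_id, *kids}
            emit(parent.clone_id, locus, "parental", config.clonal_vaf, ref_mut=0)
            for kid in kids:
                emit(kid, locus, "parental", config.clonal_vaf, ref_mut=5)

    # bulk-shared: present across other lineages, absent from references --
    if config.n_bulk_shared and daughters:
        d0 = daughters[0]
        others = {
            c.clone_id for c in manifest.other_lineage_clones(d0.clone_id)
        }
        for _ in range(config.n_bulk_shared):
            locus = placer.place_random(rng)
            carriers[locus] = set(others) | {d0.clone_id}
            emit(d0.clone_id, locus, "bulk_shared", config.clonal_vaf, ref_mut=0)

    # daughter de novo: channel-first from the genotype's mixture ----------
    sig_cols = {name: refs.column(name) for name in refs.names}
    for d in daughters:
        acts = dict(config.signature_activities.get(genotype_of[d.clone_id], {}))
        for sig in config.burst_signatures:
            if sig in acts:
                acts[sig] *= float(rng.lognormal(0.0, config.burst_sigma))
        for sig, mean_count in acts.items():
            n = int(rng.poisson(mean_count))
            if n == 0:
                continue
            channels = rng.choice(96, size=n, p=sig_cols[sig])
            for ch_idx in channels:
                locus = placer.place(rng, CHANNELS_96[int(ch_idx)])
                if locus is None:
                    continue
                vaf = (
                    config.subclone_vaf
                    if rng.random() < config.subclone_fraction
                    else config.clonal_vaf
                )
                carriers[locus].add(d.clone_id)
                emit(d.clone_id, locus, "de_novo", vaf, signature=sig)

    # injected clusters ----------------------------------------------------
    cluster_counter = 0
    for d in daughters:
        specs = [("kataegis", config.kataegis_members)] * config.n_kataegis + [
            ("omikli", config.omikli_members)
        ] * config.n_omikli
        for cls, (m_lo, m_hi) in specs:
            n_members = int(rng.integers(m_lo, m_hi + 1))
            members = _inject_cluster(rng, placer, genome, index, n_members, config)
            if members is None:
                raise RuntimeError(
                    f"could not place a {cls} cluster of {n_members} members; "
                    "genome too small for the configured IMD range"
                )
            cluster_counter += 1
            cid = f"clu{cluster_counter}"
            for locus in members:
                carriers[locus].add(d.clone_id)
                emit(d.clone_id, locus, "cluster", config.cluster_vaf,
                     signature=None, cluster_id=cid, cluster_class=cls)

    # shared-subclone switch ----------------------------------------------
    if config.shared_subclone and len(daughters) >= 2:
        sibs = manifest.daughters_of(parents[0].clone_id)[:2]
        if len(sibs) == 2:
            for _ in range(config.shared_subclone_count):
                locus = placer.place_random(rng)
                for s in sibs:
                    carriers[locus].add(s.clone_id)
                    emit(s.clone_id, locus, "shared_subclone", config.clonal_vaf)

    # artifacts ------------------------------------------------------------
    if config.artifact_fraction > 0:
        for d in daughters:
            n_real = sum(1 for r in truth_rows if r["clone"] == d.clone_id
                         and r["origin"] in ("de_novo", "cluster"))
            f = config.artifact_fraction
            n_art = int(round(n_real * f / (1 - f))) if f < 1 else n_real
            for k in range(n_art):
                locus = placer.place_random(rng)
                defect = _ARTIFACT_DEFECTS[k % len(_ARTIFACT_DEFECTS)]
                carriers[locus].add(d.clone_id)
                emit(d.clone_id, locus, "artifact", config.clonal_vaf, defect=defect)

    # genotype table -------------------------------------------------------
    loci = list(carriers)
    clone_ids = [c.clone_id for c in clones]
    mut = np.zeros((len(loci), len(clone_ids)), dtype=np.int64)
    tot = np.zeros_like(mut)
    for i, locus in enumerate(loci):
        for j, cid in enumerate(clone_ids):
            total = max(8, int(rng.poisson(config.mean_depth)))
            tot[i, j] = total
            if cid in carriers[locus]:
                mut[i, j] = max(1, int(rng.binomial(total, config.clonal_vaf)))
    genotype_table = GenotypeTable(loci, clone_ids, mut, tot)

    truth = TruthTables(
        pd.DataFrame(
            truth_rows,
            columns=["clone", "chrom", "pos", "ref", "alt", "origin",
                     "signature", "cluster_id", "cluster_class"],
        )
    )
    return records, manifest, genotype_table, truth
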