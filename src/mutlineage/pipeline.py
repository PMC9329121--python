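"""End-to-end orchestration: filter -> matrix -> enrichment -> clusters ->
attribution -> group statistics, driven by one serialisable run config."""

from __future__ import annotations

import hashlib
import json
from collections import defaultdict
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from . import catalog as cat
from . import clustered as clu
from . import enrichment as enr
from . import lineage as lin
from . import signatures as sig
from . import stats as st
from .genome import ContextIndex, ReferenceGenome, count_contexts

__all__ = ["RunConfig", "SampleMismatchError", "run_pipeline"]


class SampleMismatchError(ValueError):
    """Mutation tables contain samples absent from the manifest."""


@dataclass
class RunConfig:
    """All paths and stage parameters for one pipeline run.

    Every threshold defaults to the published analysis value; the config
    round-trips through YAML unchanged.
    """

    genome_fasta: str = ""
    mutation_table: str = ""
    manifest_yaml: str = ""
    genotype_table: str = ""
    signature_tsv: str = ""
    out_dir: str = "results"
    seed: int = 0
    log_level: str = "INFO"

    # locus filters
    asmd_max_removed: float = 130.0
    refcov_min: int = 16
    min_mut_reads: int = 1
    shared_daughter_threshold: float = 0.30

    # clustered detection
    n_background_replicates: int = 100
    imd_purity: float = 0.90
    imd_q: float = 0.01
    vaf_tolerance: float = 0.10
    regional_window: int = clu.WINDOW_SIZE

    # attribution
    nnls_add_penalty: float = sig.LOWERED_PENALTIES[0]
    nnls_remove_penalty: float = sig.LOWERED_PENALTIES[1]

    # statistics
    compare_tail: str = "one_less"
    reference_genotype: str = "WT"

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:12]


def run_pipeline(config: RunConfig, write_outputs: bool = True) -> dict:
    """Run every stage in order and return the result bundle.

    The bundle carries, per daughter clone: the filter report, de novo
    catalogue, 96-channel matrix, motif enrichments, cluster events and
    signature activities, plus the genotype-group comparisons.
    """
    genome = ReferenceGenome.from_fasta(config.genome_fasta)
    records = cat.read_mutation_table(config.mutation_table)
    manifest = lin.CloneManifest.from_yaml(config.manifest_yaml)
    genotypes = lin.GenotypeTable.from_tsv(config.genotype_table)
    refs = sig.ReferenceSignatureSet.from_tsv(config.signature_tsv, channels=cat.CHANNELS_96)

    known = {c.clone_id for c in manifest.clones}
    offenders = sorted({r.sample_id for r in records} - known)
    if offenders:
        raise SampleMismatchError(f"samples missing from manifest: {offenders}")

    by_clone: dict[str, list[cat.SBSRecord]] = defaultdict(list)
    for rec in records:
        by_clone[rec.sample_id].append(rec)

    thresholds = lin.FilterThresholds(config.asmd_max_removed, config.refcov_min)
    presence = lin.genotype_presence(genotypes, config.min_mut_reads)
    context_index = ContextIndex(genome)
    tri_inv = count_contexts(genome, flank=1)
    penta_inv = count_contexts(genome, flank=2)
    genome_mb = sum(len(s) for s in genome.sequences.values()) / 1e6

    bundle: dict = {
        "config_digest": config.digest(),
        "seed": config.seed,
        "filter_reports": {},
        "de_novo": {},
        "bulk_proxy": [],
        "enrichment": {},
        "clusters": {},
        "cluster_tmb": {},
        "activities": {},
        "comparisons": [],
        "vaf_diagnostics": {},
    }

    daughters = [c for c in manifest.clones if c.role == "daughter"]
    for clone in daughters:
        recs = by_clone.get(clone.clone_id, [])
        retained, removed = lin.apply_locus_filters(recs, thresholds)
        de_novo, removed2 = lin.derive_de_novo(
            clone.clone_id, retained, genotypes, presence, manifest
        )
        report = lin.FilterReport(
            removed={name: len(v) for name, v in {**removed, **removed2}.items()},
            retained=len(de_novo),
            bulk_proxy=sum(len(v) for v in removed2.values()),
        )
        bundle["filter_reports"][clone.clone_id] = report
        bundle["de_novo"][clone.clone_id] = de_novo
        bundle["bulk_proxy"].extend(v for vs in removed2.values() for v in vs)
        bundle["vaf_diagnostics"][clone.clone_id] = lin.vaf_clonality_diagnostic(de_novo)

    flags, shared = lin.flag_shared_daughters(
        bundle["de_novo"], config.shared_daughter_threshold
    )
    bundle["shared_daughter_flags"] = flags
    bundle["shared_fractions"] = shared

    all_de_novo = [r for recs in bundle["de_novo"].values() for r in recs]
    matrix = cat.build_matrix(
        all_de_novo, 96, genome, samples=[c.clone_id for c in daughters]
    )
    bundle["matrix96"] = matrix

    for clone in daughters:
        recs = bundle["de_novo"][clone.clone_id]
        bundle["enrichment"][clone.clone_id] = {
            motif: enr.compute_enrichment(
                recs, penta_inv if motif in ("YTCA", "RTCA") else tri_inv, motif, genome
            )
            for motif in enr.MOTIFS
        }

    for i, clone in enumerate(daughters):
        recs = bundle["de_novo"][clone.clone_id]
        background = clu.simulate_background(
            recs, genome, n=config.n_background_replicates,
            seed=config.seed * 100_003 + i, context_index=context_index,
        )
        cutoff = clu.derive_imd_cutoff(
            recs, background, config.imd_purity, config.imd_q, clone.clone_id
        )
        cutoff = clu.regional_correction(
            recs, background, cutoff, genome, context_index, config.regional_window,
            purity=config.imd_purity,
        )
        events = clu.call_clusters(recs, cutoff, config.vaf_tolerance)
        clu.partition_apobec(events, genome)
        bundle["clusters"][clone.clone_id] = {"cutoff": cutoff, "events": events}
        bundle["cluster_tmb"][clone.clone_id] = clu.clustered_tmb(events, genome_mb, genome)

    activities = []
    for clone in daughters:
        act = sig.nnls_refit(
            matrix.row(clone.clone_id), refs,
            config.nnls_add_penalty, config.nnls_remove_penalty,
            sample_id=clone.clone_id,
        )
        activities.append(act)
        bundle["activities"][clone.clone_id] = act

    # genotype-group comparisons over per-signature activities, one BH family
    genotype_of = {c.clone_id: (c.genotype or "NA") for c in daughters}
    eligible = [c.clone_id for c in daughters if c.clone_id not in flags]
    groups: dict[str, tuple[list[float], list[float]]] = {}
    genos = sorted({genotype_of[c] for c in eligible})
    for sname in refs.names:
        j = refs.names.index(sname)
        per_geno = {
            g: [float(bundle["activities"][c].activities[j]) for c in eligible
                if genotype_of[c] == g]
            for g in genos
        }
        ref_g = config.reference_genotype
        if ref_g not in per_geno:
            continue
        for g in genos:
            if g == ref_g or not per_geno[g] or not per_geno[ref_g]:
                continue
            groups[f"{sname}:{g}_vs_{ref_g}"] = (per_geno[g], per_geno[ref_g])
    if groups:
        bundle["comparisons"] = st.compare_groups(groups, config.compare_tail)

    if write_outputs:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        meta = {"config_digest": bundle["config_digest"], "seed": config.seed}
        (out / "run_meta.json").write_text(json.dumps(meta, indent=2))
        config.to_yaml(out / "config_echo.yaml")
        matrix.to_tsv(out / "matrix_96.tsv")
        sig.activities_to_tsv(activities, out / "activities.tsv")
        if bundle["comparisons"]:
            st.comparisons_to_tsv(bundle["comparisons"], out / "comparisons.tsv")
        for clone_id, rep in bundle["filter_reports"].items():
            rep.to_json(out / f"filter_report_{clone_id}.json")
        for clone_id, payload in bundle["clusters"].items():
            clu.events_to_tsv(payload["events"], out / f"clusters_{clone_id}.tsv")
        cat.write_mutation_table(bundle["bulk_proxy"], out / "bulk_proxy.tsv")
        enr_rows = []
        for clone_id, motifs in bundle["enrichment"].items():
            for motif, res in motifs.items():
                enr_rows.append({"clone": clone_id, **res.__dict__})
        import pandas as pd

        pd.DataFrame(enr_rows).to_csv(out / "enrichment.tsv", sep="\t", index=False)
    return bundle
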