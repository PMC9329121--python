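from collections import Counter

import numpy as np
import pytest

from mutlineage.catalog import build_matrix
from mutlineage.clustered import (
    ImdCutoff,
    call_clusters,
    clustered_tmb,
    derive_imd_cutoff,
    events_to_tsv,
    is_apobec3_member,
    partition_apobec,
    rainfall_data,
    regional_correction,
    simulate_background,
)
from mutlineage.genome import ContextIndex, ReferenceGenome, context_at
from mutlineage.simulate import SimulationConfig, _Placer, _inject_cluster, simulate_genome

from .conftest import make_record


def scatter_records(genome, n, seed, vaf=0.5, sample="s"):
    rng = np.random.default_rng(seed)
    placer = _Placer(genome, ContextIndex(genome))
    recs = []
    for _ in range(n):
        chrom, pos, ref, alt = placer.place_random(rng)
        m = max(2, int(rng.binomial(40, vaf)))
        recs.append(
            make_record(chrom, pos, ref, alt, sample_id=sample,
                        mut_fwd=m - m // 2, mut_rev=m // 2, depth=40)
        )
    return recs, placer


class TestSimulateBackground:
    def test_replicate_fidelity(self, genome_100kb):
        recs, _ = scatter_records(genome_100kb, 200, seed=1)
        bg = simulate_background(recs, genome_100kb, n=10, seed=2)
        obs_by_chrom = Counter(r.chrom for r in recs)
        obs_contexts = Counter(
            (r.chrom, context_at(genome_100kb, r.chrom, r.pos, 1)[0]) for r in recs
        )
        for rep in bg.positions:
            # per-chromosome counts preserved exactly
            assert {c: p.size for c, p in rep.items()} == dict(obs_by_chrom)
            # per-chromosome context multiset preserved exactly
            sim_contexts = Counter(
                (chrom, context_at(genome_100kb, chrom, int(p), 1)[0])
                for chrom, pos in rep.items()
                for p in pos
            )
            assert sim_contexts == obs_contexts

    def test_forced_unique_context_stays(self):
        # context ACA occurs exactly once; its mutation cannot move
        genome = ReferenceGenome({"c": "AACAA"})
        rec = make_record("c", 3, "C", "T")
        bg = simulate_background([rec], genome, n=5, seed=3)
        for rep in bg.positions:
            assert rep["c"].tolist() == [3]
        assert bg.n_kept_at_origin == 5

    def test_deterministic_from_seed(self, genome_100kb):
        recs, _ = scatter_records(genome_100kb, 50, seed=4)
        a = simulate_background(recs, genome_100kb, n=3, seed=9)
        b = simulate_background(recs, genome_100kb, n=3, seed=9)
        for ra, rb in zip(a.positions, b.positions):
            for chrom in ra:
                assert np.array_equal(ra[chrom], rb[chrom])

    def test_no_duplicate_positions_within_replicate(self, genome_100kb):
        recs, _ = scatter_records(genome_100kb, 300, seed=5)
        bg = simulate_background(recs, genome_100kb, n=5, seed=6)
        for rep in bg.positions:
            for chrom, pos in rep.items():
                assert np.unique(pos).size == pos.size

    def test_96_catalog_preserved(self, genome_100kb):
        recs, _ = scatter_records(genome_100kb, 150, seed=7)
        bg = simulate_background(recs, genome_100kb, n=3, seed=8)
        obs = build_matrix(recs, 96, genome_100kb).counts
        for rep in bg.positions:
            moved = []
            taken = {c: list(p) for c, p in rep.items()}
            # reassign simulated positions to records chromosome-wise; the
            # catalogue only depends on (context, alt) so order is irrelevant
            by_chrom: dict[str, list] = {}
            for r in recs:
                by_chrom.setdefault(r.chrom, []).append(r)
            for chrom, rs in by_chrom.items():
                rs_sorted = sorted(rs, key=lambda r: context_at(genome_100kb, r.chrom, r.pos, 1)[0])
                ps_sorted = sorted(
                    taken[chrom], key=lambda p: context_at(genome_100kb, chrom, int(p), 1)[0]
                )
                for r, p in zip(rs_sorted, ps_sorted):
                    ctx_r = context_at(genome_100kb, chrom, r.pos, 1)[0]
                    ctx_p, collapsed = context_at(genome_100kb, chrom, int(p), 1)
                    assert ctx_r == ctx_p
                    pyr_alt = r.alt if r.ref in "CT" else {"A": "T", "C": "G", "G": "C", "T": "A"}[r.alt]
                    ref = genome_100kb.base_at(chrom, int(p))
                    alt = pyr_alt if ref in "CT" else {"A": "T", "C": "G", "G": "C", "T": "A"}[pyr_alt]
                    moved.append(make_record(chrom, int(p), ref, alt, sample_id=r.sample_id))
            sim = build_matrix(moved, 96, genome_100kb).counts
            assert np.array_equal(sim, obs)


class TestImdCutoff:
    def test_null_catalog_near_zero_clusters(self, genome_1mb):
        recs, _ = scatter_records(genome_1mb, 300, seed=10)
        bg = simulate_background(recs, genome_1mb, n=20, seed=11)
        cut = derive_imd_cutoff(recs, bg)
        events = call_clusters(recs, cut)
        clustered = sum(e.n_members for e in events)
        assert clustered / len(recs) <= 0.02

    def test_purity_one_limit(self, genome_1mb):
        recs, _ = scatter_records(genome_1mb, 300, seed=12)
        bg = simulate_background(recs, genome_1mb, n=20, seed=13)
        cut = derive_imd_cutoff(recs, bg, purity=1.0)
        min_sim = min(
            int(bg.pooled_imds(r).min()) for r in range(bg.n_replicates)
            if bg.pooled_imds(r).size
        )
        assert cut.global_cutoff <= min_sim

    def test_fewer_than_two_mutations(self, genome_1mb):
        recs, _ = scatter_records(genome_1mb, 1, seed=14)
        bg = simulate_background(recs, genome_1mb, n=5, seed=15)
        cut = derive_imd_cutoff(recs, bg)
        assert cut.global_cutoff == 0 and cut.achieved_purity is None

    def test_recovery_with_injected_clusters(self, genome_1mb):
        cfg = SimulationConfig(chromosomes={"c1": 1_000_000})
        rng = np.random.default_rng(16)
        recs, placer = scatter_records(genome_1mb, 150, seed=16)
        index = ContextIndex(genome_1mb)
        truth = []
        for _ in range(6):
            members = _inject_cluster(rng, placer, genome_1mb, index, 5, cfg)
            assert members is not None
            truth.append(members)
            for chrom, pos, ref, alt in members:
                recs.append(make_record(chrom, pos, ref, alt, sample_id="s"))
        bg = simulate_background(recs, genome_1mb, n=50, seed=17)
        cut = derive_imd_cutoff(recs, bg)
        assert cut.global_cutoff > 8  # injected IMDs are <= 8
        assert cut.achieved_purity is not None and cut.achieved_purity >= 0.90
        events = call_clusters(recs, cut)
        called = {(m.chrom, m.pos): e.cls for e in events for m in e.members}
        recovered = sum(
            all(called.get((c, p)) == "kataegis" for c, p, _, _ in members)
            for members in truth
        )
        assert recovered >= 5


class TestRegionalCorrection:
    def test_homogeneous_no_overrides(self, genome_1mb):
        recs, _ = scatter_records(genome_1mb, 300, seed=18)
        bg = simulate_background(recs, genome_1mb, n=20, seed=19)
        cut = derive_imd_cutoff(recs, bg)
        corrected = regional_correction(
            recs, bg, cut, genome_1mb, window=100_000
        )
        assert corrected.window_cutoffs == {}

    def test_dense_window_cutoff_not_above_global(self, genome_1mb):
        rng = np.random.default_rng(20)
        recs, placer = scatter_records(genome_1mb, 200, seed=20)
        # pile 800 extra mutations into the first 100-kb tile
        index = ContextIndex(genome_1mb)
        added = 0
        while added < 800:
            pos = int(rng.integers(3, 100_000))
            if ("c1", pos) in placer.used:
                continue
            placer.used.add(("c1", pos))
            ref = genome_1mb.base_at("c1", pos)
            alt = str(rng.choice([b for b in "ACGT" if b != ref]))
            recs.append(make_record("c1", pos, ref, alt, sample_id="s"))
            added += 1
        bg = simulate_background(recs, genome_1mb, n=20, seed=21)
        cut = derive_imd_cutoff(recs, bg)
        corrected = regional_correction(recs, bg, cut, genome_1mb, window=100_000)
        assert ("c1", 0) in corrected.window_cutoffs
        assert corrected.window_cutoffs[("c1", 0)] <= corrected.global_cutoff


class TestCallClusters:
    def vafrec(self, pos, vaf, chrom="c"):
        m = round(40 * vaf)
        return make_record(chrom, pos, "C", "T", mut_fwd=m - m // 2, mut_rev=m // 2, depth=40)

    def test_kataegis_example(self):
        recs = [self.vafrec(p, v) for p, v in
                [(100, 0.50), (250, 0.52), (400, 0.47), (480, 0.49)]]
        events = call_clusters(recs, ImdCutoff("s", 1000, 0.95))
        assert len(events) == 1
        assert events[0].cls == "kataegis" and events[0].n_members == 4

    def test_doublet_example(self):
        recs = [self.vafrec(500, 0.40), self.vafrec(501, 0.42)]
        events = call_clusters(recs, ImdCutoff("s", 1000, 0.95))
        assert events[0].cls == "doublet"

    def test_inconsistent_vaf_other(self):
        recs = [self.vafrec(1000, 0.50), self.vafrec(1600, 0.20)]
        events = call_clusters(recs, ImdCutoff("s", 5000, 0.95))
        assert events[0].cls == "other" and not events[0].vaf_consistent

    def test_omikli_and_multibase(self):
        events = call_clusters(
            [self.vafrec(10, 0.5), self.vafrec(40, 0.5), self.vafrec(70, 0.5)],
            ImdCutoff("s", 1000, 0.95),
        )
        assert events[0].cls == "omikli"
        events = call_clusters(
            [self.vafrec(10, 0.5), self.vafrec(11, 0.5), self.vafrec(12, 0.5)],
            ImdCutoff("s", 1000, 0.95),
        )
        assert events[0].cls == "multibase"

    def test_zero_cutoff_no_events(self):
        recs = [self.vafrec(10, 0.5), self.vafrec(11, 0.5)]
        assert call_clusters(recs, ImdCutoff("s", 0, None)) == []

    def test_partition_property(self, genome_1mb):
        recs, _ = scatter_records(genome_1mb, 500, seed=22)
        events = call_clusters(recs, ImdCutoff("s", 3000, 0.95))
        seen = set()
        for e in events:
            for m in e.members:
                key = (m.chrom, m.pos)
                assert key not in seen  # each SBS in at most one event
                seen.add(key)
        assert sum(e.n_members for e in events) == len(seen)


class TestApobecPartition:
    def test_member_classification(self, genome_100kb):
        # find a TCN cytosine and a non-TCN cytosine
        index = ContextIndex(genome_100kb)
        tc_pos = int(index.positions("c1", "TCA")[0])
        ac_pos = int(index.positions("c1", "ACT")[0])
        tc_ref = genome_100kb.base_at("c1", tc_pos)
        ac_ref = genome_100kb.base_at("c1", ac_pos)
        tc_rec = make_record("c1", tc_pos, tc_ref, "T" if tc_ref == "C" else "A")
        ac_rec = make_record("c1", ac_pos, ac_ref, "G" if ac_ref == "C" else "C")
        assert is_apobec3_member(tc_rec, genome_100kb)
        assert not is_apobec3_member(ac_rec, genome_100kb)

    def test_event_counts(self, genome_100kb):
        index = ContextIndex(genome_100kb)
        tcs = [int(p) for p in index.positions("c1", "TCT")[:3]]
        other = int(index.positions("c1", "CCC")[0])
        members = []
        for p in sorted(tcs + [other]):
            ref = genome_100kb.base_at("c1", p)
            alt = "T" if ref == "C" else "A"
            members.append(make_record("c1", p, ref, alt))
        from mutlineage.clustered import ClusterEvent

        ev = ClusterEvent("c1", members, [1, 1, 1], "kataegis", True)
        tallies = partition_apobec([ev], genome_100kb)
        assert ev.apobec3_member_count == 3
        assert tallies == {"apobec3": 3, "non_apobec3": 1}


class TestClusteredTmb:
    def make_events(self, n_events, members_each):
        from mutlineage.clustered import ClusterEvent

        events = []
        for i in range(n_events):
            ms = [make_record("c", 1000 * i + j + 2) for j in range(members_each)]
            events.append(ClusterEvent("c", ms, [1] * (members_each - 1), "kataegis", True))
        return events

    def test_simple_rate(self):
        out = clustered_tmb(self.make_events(5, 6), 10.0)
        assert out["sbs_tmb"]["total"] == pytest.approx(3.0)  # 30 SBSs / 10 Mb
        assert out["event_tmb"]["total"] == pytest.approx(0.5)
        assert out["sbs_tmb"]["kataegis"] == pytest.approx(3.0)

    def test_no_events(self):
        out = clustered_tmb([], 10.0)
        assert all(v == 0 for v in out["sbs_tmb"].values())

    def test_zero_genome_size(self):
        with pytest.raises(ValueError):
            clustered_tmb([], 0.0)


class TestExports:
    def test_rainfall_and_events_tsv(self, tmp_path, genome_1mb):
        recs, _ = scatter_records(genome_1mb, 100, seed=23)
        events = call_clusters(recs, ImdCutoff("s", 20_000, 0.95))
        df = rainfall_data(recs, events)
        assert len(df) == len(recs) - 1  # one IMD per consecutive pair
        assert set(df.columns) == {"chrom", "pos", "imd", "log10_imd", "cluster_class"}
        path = tmp_path / "events.tsv"
        events_to_tsv(events, path)
        assert path.read_text().startswith("chrom\tstart\tend")
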