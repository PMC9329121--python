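import numpy as np
import pytest

from mutlineage.lineage import (
    Clone,
    CloneManifest,
    FilterThresholds,
    GenotypeTable,
    MissingQualityFieldError,
    UnknownCloneError,
    apply_locus_filters,
    derive_de_novo,
    flag_shared_daughters,
    genotype_presence,
    vaf_clonality_diagnostic,
)

from .conftest import make_record


def small_manifest() -> CloneManifest:
    return CloneManifest(
        "CL-1",
        [
            Clone("P1", "parent", "L1", None, "normal"),
            Clone("D1.1", "daughter", "L1", "P1", "P1"),
            Clone("D1.2", "daughter", "L1", "P1", "P1"),
            Clone("P2", "parent", "L2", None, "normal"),
            Clone("D2.1", "daughter", "L2", "P2", "P2"),
            Clone("D2.2", "daughter", "L2", "P2", "P2"),
            Clone("P3", "parent", "L3", None, "normal"),
            Clone("D3.1", "daughter", "L3", "P3", "P3"),
        ],
    )


class TestLocusFilters:
    def test_asmd_boundary_exactly_130_removed(self):
        retained, removed = apply_locus_filters([make_record(asmd=130.0)])
        assert not retained and len(removed["f1_asmd"]) == 1

    def test_asmd_just_above_retained(self):
        retained, _ = apply_locus_filters([make_record(asmd=130.01)])
        assert len(retained) == 1

    def test_refcov_boundary_15_removed(self):
        retained, removed = apply_locus_filters([make_record(ref_sample_depth=15)])
        assert not retained and len(removed["f3_refcov"]) == 1

    def test_refcov_16_retained(self):
        retained, _ = apply_locus_filters([make_record(ref_sample_depth=16)])
        assert len(retained) == 1

    def test_one_record_per_bucket(self):
        records = [
            make_record(pass_flag=False),
            make_record(asmd=100.0),
            make_record(clpm=0.5),
            make_record(ref_sample_depth=10),
            make_record(mut_fwd=15, mut_rev=0),
            make_record(),
        ]
        retained, removed = apply_locus_filters(records)
        assert len(retained) == 1
        assert {k: len(v) for k, v in removed.items()} == {
            "f0_nonpass": 1, "f1_asmd": 1, "f2_clpm": 1, "f3_refcov": 1, "f4_direction": 1,
        }

    def test_conservation_and_order_independence(self):
        rng = np.random.default_rng(0)
        records = [
            make_record(
                pos=int(i + 2),
                asmd=float(rng.uniform(100, 160)),
                clpm=float(rng.choice([0.0, 0.0, 1.0])),
                ref_sample_depth=int(rng.integers(10, 40)),
                mut_fwd=int(rng.integers(0, 10)),
                mut_rev=int(rng.integers(0, 10)),
                depth=30,
                pass_flag=bool(rng.random() < 0.9),
            )
            for i in range(2000)
        ]
        retained, removed = apply_locus_filters(records)
        assert len(retained) + sum(len(v) for v in removed.values()) == len(records)
        # retained set equals the order-free conjunction of all predicates
        expected = [
            r for r in records
            if r.pass_flag and r.asmd > 130 and r.clpm == 0
            and r.ref_sample_depth >= 16 and r.mut_fwd >= 1 and r.mut_rev >= 1
        ]
        assert retained == expected

    def test_missing_quality_field(self):
        with pytest.raises(MissingQualityFieldError):
            apply_locus_filters([make_record(asmd=float("nan"))])

    def test_custom_thresholds(self):
        thr = FilterThresholds(asmd_max_removed=90, refcov_min=5)
        retained, _ = apply_locus_filters(
            [make_record(asmd=100, ref_sample_depth=6)], thr
        )
        assert len(retained) == 1


class TestGenotypePresence:
    def make_table(self):
        loci = [("c", 10, "C", "T"), ("c", 20, "A", "G")]
        clones = ["P1", "D1.1"]
        mut = np.array([[0, 1], [3, 0]])
        tot = np.array([[30, 30], [30, 30]])
        return GenotypeTable(loci, clones, mut, tot)

    def test_single_read_suffices(self):
        presence = genotype_presence(self.make_table())
        assert presence.tolist() == [[False, True], [True, False]]

    def test_min_reads_configurable(self):
        presence = genotype_presence(self.make_table(), min_mut_reads=2)
        assert presence.tolist() == [[False, False], [True, False]]

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            GenotypeTable([("c", 1, "A", "C")], ["x"], np.array([[5]]), np.array([[3]]))

    def test_tsv_round_trip(self, tmp_path):
        table = self.make_table()
        path = tmp_path / "gt.tsv"
        table.to_tsv(path)
        back = GenotypeTable.from_tsv(path)
        assert back.loci == table.loci
        assert back.clones == table.clones
        assert np.array_equal(back.mut_reads, table.mut_reads)


class TestDeriveDeNovo:
    def build(self, mut_rows):
        """Genotype table over clones of small_manifest with given mut counts."""
        manifest = small_manifest()
        clones = [c.clone_id for c in manifest.clones]
        loci = [("c", 100 + i, "C", "T") for i in range(len(mut_rows))]
        mut = np.array(mut_rows)
        tot = np.full_like(mut, 30)
        table = GenotypeTable(loci, clones, mut, tot)
        records = [make_record("c", 100 + i, "C", "T", sample_id="D1.1") for i in range(len(loci))]
        return manifest, table, records

    def test_reference_read_removes(self):
        # locus present at 2 reads in P1 (the reference of D1.1)
        manifest, table, records = self.build([[2, 0, 0, 0, 0, 0, 0, 0]])
        presence = genotype_presence(table)
        de_novo, removed = derive_de_novo("D1.1", records, table, presence, manifest)
        assert not de_novo and len(removed["f5_ref_reads"]) == 1

    def test_strict_majority_of_other_lineages(self):
        # other-lineage clones: P2, D2.1, D2.2, P3, D3.1 (5 clones)
        # present in 3/5 (60% > 50%) -> removed; in 2/5 (40%) -> retained
        manifest, table, records = self.build(
            [
                [0, 0, 0, 5, 5, 5, 0, 0],  # 3 of 5 -> f6
                [0, 0, 0, 5, 5, 0, 0, 0],  # 2 of 5 -> retained
            ]
        )
        presence = genotype_presence(table)
        de_novo, removed = derive_de_novo("D1.1", records, table, presence, manifest)
        assert len(de_novo) == 1 and de_novo[0].pos == 101
        assert len(removed["f6_other_lineages"]) == 1

    def test_exact_half_retained(self):
        manifest = CloneManifest(
            "CL-2",
            [
                Clone("P1", "parent", "L1", None, "normal"),
                Clone("D1.1", "daughter", "L1", "P1", "P1"),
                Clone("P2", "parent", "L2", None, "normal"),
                Clone("D2.1", "daughter", "L2", "P2", "P2"),
                Clone("P3", "parent", "L3", None, "normal"),
                Clone("D3.1", "daughter", "L3", "P3", "P3"),
            ],
        )
        clones = [c.clone_id for c in manifest.clones]
        loci = [("c", 100, "C", "T")]
        mut = np.array([[0, 0, 5, 0, 5, 0]])  # 2 of 4 other-lineage clones = 50%
        table = GenotypeTable(loci, clones, mut, np.full_like(mut, 30))
        records = [make_record("c", 100, "C", "T", sample_id="D1.1")]
        de_novo, removed = derive_de_novo(
            "D1.1", records, table, genotype_presence(table), manifest
        )
        assert len(de_novo) == 1
        assert not removed["f6_other_lineages"]

    def test_ref_sample_mut_field_triggers_f5(self):
        manifest, table, _ = self.build([[0, 0, 0, 0, 0, 0, 0, 0]])
        rec = make_record("c", 100, "C", "T", sample_id="D1.1", ref_sample_mut=2)
        de_novo, removed = derive_de_novo(
            "D1.1", [rec], table, genotype_presence(table), manifest
        )
        assert not de_novo and len(removed["f5_ref_reads"]) == 1

    def test_unknown_clone(self):
        manifest, table, records = self.build([[0] * 8])
        with pytest.raises(UnknownCloneError):
            derive_de_novo("nope", records, table, genotype_presence(table), manifest)

    def test_bulk_proxy_partition(self):
        manifest, table, records = self.build(
            [[2, 0, 0, 0, 0, 0, 0, 0], [0, 0, 0, 5, 5, 5, 5, 5], [0] * 8]
        )
        presence = genotype_presence(table)
        de_novo, removed = derive_de_novo("D1.1", records, table, presence, manifest)
        bulk = removed["f5_ref_reads"] + removed["f6_other_lineages"]
        assert len(de_novo) == 1 and len(bulk) == 2
        assert {r.pos for r in bulk} | {r.pos for r in de_novo} == {100, 101, 102}


class TestSharedDaughters:
    def catalog(self, positions, sample):
        return [make_record("c", p, "C", "T", sample_id=sample) for p in positions]

    def test_identical_catalogs_both_flagged(self):
        cats = {"a": self.catalog(range(10, 60), "a"), "b": self.catalog(range(10, 60), "b")}
        flags, frac = flag_shared_daughters(cats)
        assert flags == {"a", "b"}
        assert frac.loc["a", "b"] == 1.0

    def test_disjoint_none_flagged(self):
        cats = {"a": self.catalog(range(10, 30), "a"), "b": self.catalog(range(100, 120), "b")}
        flags, frac = flag_shared_daughters(cats)
        assert not flags
        assert frac.loc["a", "b"] == 0.0

    def test_forty_percent_shared_flagged(self):
        shared = list(range(1000, 1040))
        cats = {
            "a": self.catalog(shared + list(range(2000, 2060)), "a"),  # 40/100
            "b": self.catalog(shared + list(range(3000, 3200)), "b"),  # 40/240
        }
        flags, frac = flag_shared_daughters(cats)
        assert frac.loc["a", "b"] == pytest.approx(0.40)
        assert "a" in flags and "b" not in flags  # asymmetric denominator

    def test_singleton(self):
        flags, _ = flag_shared_daughters({"a": self.catalog(range(5, 10), "a")})
        assert flags == set()


class TestVafDiagnostic:
    def test_clonal_unimodal(self):
        rng = np.random.default_rng(1)
        recs = []
        for _ in range(300):
            m = int(rng.binomial(30, 0.5))
            m = min(max(m, 2), 28)
            recs.append(make_record(mut_fwd=m - 1, mut_rev=1, depth=30))
        out = vaf_clonality_diagnostic(recs)
        assert out["mode_count"] == 1
        assert out["label"] == "clonal"

    def test_bimodal_mixture(self):
        rng = np.random.default_rng(2)
        recs = []
        for vaf in (0.5, 0.2):
            for _ in range(300):
                m = int(rng.binomial(60, vaf))
                m = min(max(m, 2), 58)
                recs.append(make_record(mut_fwd=m - 1, mut_rev=1, depth=60))
        out = vaf_clonality_diagnostic(recs)
        assert out["mode_count"] >= 2
        assert out["label"] == "possible subclonality"

    def test_underpowered(self):
        recs = [make_record() for _ in range(10)]
        out = vaf_clonality_diagnostic(recs)
        assert out["label"] == "underpowered"
        assert out["mode_count"] is None


class TestManifest:
    def test_yaml_round_trip(self, tmp_path):
        manifest = small_manifest()
        path = tmp_path / "m.yaml"
        manifest.to_yaml(path)
        back = CloneManifest.from_yaml(path)
        assert back.cell_line == manifest.cell_line
        assert [c.clone_id for c in back.clones] == [c.clone_id for c in manifest.clones]

    def test_orphan_daughter_rejected(self):
        with pytest.raises(ValueError, match="unknown parent"):
            CloneManifest("x", [Clone("D1", "daughter", "L1", "ghost", "ghost")])

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            CloneManifest(
                "x",
                [Clone("P1", "parent", "L1"), Clone("P1", "parent", "L1")],
            )

    def test_other_lineage_clones(self):
        manifest = small_manifest()
        others = {c.clone_id for c in manifest.other_lineage_clones("D1.1")}
        assert others == {"P2", "D2.1", "D2.2", "P3", "D3.1"}
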