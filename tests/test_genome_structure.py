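import numpy as np
import pandas as pd
import pytest

from polytetra import genome_structure as gs
from polytetra.io_core import IntervalSet, ValidationError
from polytetra.synthetic_data import SynthConfig, synth_gene_annotations


def iset(rows):
    return IntervalSet(
        pd.DataFrame(rows, columns=["chrom", "start", "end", "label"])
    )


class TestAlleleSummary:
    def test_study_scale_arithmetic(self):
        # 29,817 genes totalling 103,217 alleles
        counts = {}
        gid = 0
        for n, k in ((20_626, 4), (4_516, 3), (2_490, 2), (2_185, 1)):
            for _ in range(n):
                counts[f"g{gid}"] = k
                gid += 1
        out = gs.allele_summary(counts)
        by_class = out.set_index("allele_class")
        assert by_class.loc["4", "percent"] == 69.18
        assert by_class.loc["3", "percent"] == 15.15
        assert by_class.loc["2", "percent"] == 8.35
        # 2185/29817 = 7.3279% (reported elsewhere as 7.32, a truncation)
        assert by_class.loc["1", "percent"] == 7.33
        assert out.attrs["total_alleles"] == 103_217
        assert out.attrs["mean_alleles_per_gene"] == 3.46

    def test_single_gene(self):
        out = gs.allele_summary({"g": 4})
        assert out.set_index("allele_class").loc["4", "percent"] == 100.0
        assert out.attrs["mean_alleles_per_gene"] == 4.0

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            gs.allele_summary({})


class TestGroupIdenticalSvs:
    AMAP = {"A1": 1, "B1": 1, "C1": 1, "D1": 1, "A2": 2}

    @staticmethod
    def sv(chrom, start, end, sv_type, mono):
        return {
            "chrom": chrom, "start": start, "end": end,
            "sv_type": sv_type, "monoploid": mono,
        }

    def test_single_sv_singleton_class(self):
        out = gs.group_identical_svs(
            pd.DataFrame([self.sv("A1", 0, 100, "inversion", "A")]), self.AMAP
        )
        assert out.loc[0, "presence_class"] == "A"

    def test_fifty_percent_overlap_rule(self):
        # [0,100) vs [40,140): overlap 60 >= 50% of the shorter (100)
        out = gs.group_identical_svs(
            pd.DataFrame(
                [
                    self.sv("A1", 0, 100, "duplication", "A"),
                    self.sv("B1", 40, 140, "duplication", "B"),
                ]
            ),
            self.AMAP,
        )
        assert out["group_id"].nunique() == 1
        assert set(out["presence_class"]) == {"AB"}

    def test_insufficient_overlap_separate_groups(self):
        out = gs.group_identical_svs(
            pd.DataFrame(
                [
                    self.sv("A1", 0, 100, "duplication", "A"),
                    self.sv("B1", 60, 160, "duplication", "B"),
                ]
            ),
            self.AMAP,
        )
        assert out["group_id"].nunique() == 2

    def test_type_mismatch_separates(self):
        out = gs.group_identical_svs(
            pd.DataFrame(
                [
                    self.sv("A1", 0, 100, "inversion", "A"),
                    self.sv("B1", 0, 100, "translocation", "B"),
                ]
            ),
            self.AMAP,
        )
        assert out["group_id"].nunique() == 2

    def test_chaining_transitive_closure(self):
        # A-B overlap and B-C overlap chain into one group even though A-C
        # overlap alone is below 50%
        out = gs.group_identical_svs(
            pd.DataFrame(
                [
                    self.sv("A1", 0, 100, "inversion", "A"),
                    self.sv("B1", 50, 150, "inversion", "B"),
                    self.sv("C1", 100, 200, "inversion", "C"),
                ]
            ),
            self.AMAP,
        )
        assert out["group_id"].nunique() == 1
        assert set(out["presence_class"]) == {"ABC"}

    def test_partition_property(self):
        rng = np.random.default_rng(0)
        rows = [
            self.sv(
                rng.choice(["A1", "B1", "C1", "D1"]),
                int(s := rng.integers(0, 5000)),
                int(s + rng.integers(50, 500)),
                rng.choice(["inversion", "translocation", "duplication"]),
                rng.choice(list("ABCD")),
            )
            for _ in range(60)
        ]
        out = gs.group_identical_svs(pd.DataFrame(rows), self.AMAP)
        assert out["group_id"].notna().all()
        classes = set(out["presence_class"])
        assert len(classes) <= 15
        assert all(set(c) <= set("ABCD") and c for c in classes)

    def test_unknown_chromosome_rejected(self):
        with pytest.raises(ValidationError):
            gs.group_identical_svs(
                pd.DataFrame([self.sv("Z9", 0, 100, "inversion", "A")]),
                self.AMAP,
            )


class TestGeneSvClassification:
    GENES = iset([("chr1", 100, 200, "g1")])

    def test_overlap_is_within(self):
        cls = gs.classify_gene_sv(self.GENES, iset([("chr1", 150, 300, "sv")]))
        assert cls["g1"] == "within_sv"

    def test_gap_at_margin_is_near(self):
        # gap 1900 and exactly 2000 are near; 2001 is far
        assert (
            gs.classify_gene_sv(self.GENES, iset([("chr1", 2100, 2300, "sv")]))["g1"]
            == "near_sv"
        )
        assert (
            gs.classify_gene_sv(self.GENES, iset([("chr1", 2200, 2300, "sv")]))["g1"]
            == "near_sv"
        )
        assert (
            gs.classify_gene_sv(self.GENES, iset([("chr1", 2201, 2300, "sv")]))["g1"]
            == "far"
        )

    def test_upstream_gap_symmetric(self):
        genes = iset([("chr1", 2050, 2150, "g1")])
        assert (
            gs.classify_gene_sv(genes, iset([("chr1", 0, 50, "sv")]))["g1"]
            == "near_sv"
        )
        assert (
            gs.classify_gene_sv(genes, iset([("chr1", 0, 49, "sv")]))["g1"]
            == "far"
        )

    def test_exhaustive_and_exclusive(self):
        rng = np.random.default_rng(1)
        genes = iset(
            [("chr1", int(s), int(s + 100), f"g{i}")
             for i, s in enumerate(rng.integers(0, 50_000, size=40))]
        )
        svs = iset(
            [("chr1", int(s), int(s + 200), "sv")
             for s in rng.integers(0, 50_000, size=10)]
        )
        cls = gs.classify_gene_sv(genes, svs)
        assert set(cls.unique()) <= {"within_sv", "near_sv", "far"}
        assert len(cls) == 40


class TestTeOverlap:
    def test_no_tes_all_false(self):
        genes = iset([("chr1", 0, 100, "g1")])
        flags = gs.flag_te_overlap(genes, iset([]))
        assert not flags.any()

    def test_te_inside_gene_span(self):
        genes = iset([("chr1", 0, 1000, "g1")])
        assert gs.flag_te_overlap(genes, iset([("chr1", 400, 500, "te")]))["g1"]

    def test_half_open_adjacency_excluded(self):
        genes = iset([("chr1", 0, 100, "g1")])
        assert not gs.flag_te_overlap(genes, iset([("chr1", 100, 200, "te")]))["g1"]


class TestRbh:
    @staticmethod
    def hits(rows):
        return pd.DataFrame(rows, columns=["query_id", "subject_id", "score"])

    def test_symmetric_best_hits(self):
        ab = self.hits([("a", "b", 100.0)])
        ba = self.hits([("b", "a", 90.0)])
        assert gs.reciprocal_best_hits(ab, ba) == [("a", "b")]

    def test_asymmetric_best_hits_excluded(self):
        ab = self.hits([("a", "b", 100.0)])
        ba = self.hits([("b", "c", 90.0), ("b", "a", 50.0)])
        assert gs.reciprocal_best_hits(ab, ba) == []

    def test_score_tie_broken_lexicographically(self):
        ab = self.hits([("a", "b2", 100.0), ("a", "b1", 100.0)])
        ba = self.hits([("b1", "a", 80.0), ("b2", "a", 80.0)])
        assert gs.reciprocal_best_hits(ab, ba) == [("a", "b1")]


class TestFisher:
    def test_balanced_table(self):
        res = gs.fisher_enrichment(5, 5, 5, 5)
        assert res.odds_ratio == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1.0)

    def test_translocation_vs_inversion_loss(self):
        # printed loss counts: translocations 533 of 939, inversions 413 of 1546
        res = gs.fisher_enrichment(533, 406, 413, 1133)
        assert res.odds_ratio == pytest.approx(3.60, abs=0.01)
        assert res.p_value < 0.01

    def test_extreme_table_matches_enumeration(self):
        from math import comb

        res = gs.fisher_enrichment(10, 0, 0, 10)
        # only tables x=a with prob <= observed: x=10 and x=0
        p_exact = 2 * comb(10, 10) * comb(10, 0) / comb(20, 10)
        assert res.p_value == pytest.approx(p_exact, rel=1e-9)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValidationError):
            gs.fisher_enrichment(0, 0, 5, 5)


class TestLossAssociationReport:
    @staticmethod
    def gene_frame(n, rng, loss_p=0.3):
        loss = rng.random(n) < loss_p
        return pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(n)],
                "n_alleles": np.where(loss, 2, 4),
                "sv_class": rng.choice(
                    ["within_sv", "near_sv", "far"], size=n
                ),
                "te_overlap": rng.random(n) < 0.5,
                "ppi": rng.random(n) < 0.7,
            }
        )

    def test_null_association_or_near_one(self):
        rng = np.random.default_rng(2)
        rep = gs.loss_association_report(self.gene_frame(4000, rng))
        for _, row in rep.iterrows():
            assert 0.7 < row["odds_ratio"] < 1.4

    def test_merged_and_separate_sv_contrasts_present(self):
        rng = np.random.default_rng(3)
        rep = gs.loss_association_report(self.gene_frame(500, rng))
        assert {"sv_within_or_near", "sv_within", "te_overlap", "ppi"} == set(
            rep["contrast"]
        )

    def test_all_loss_degenerate(self):
        rng = np.random.default_rng(4)
        frame = self.gene_frame(100, rng, loss_p=1.1)
        with pytest.raises(ValidationError):
            gs.loss_association_report(frame)


class TestSyntheticAnnotations:
    def test_planted_sv_odds_ratio_recovered(self):
        cfg = SynthConfig(seed=5, n_genes=5000, or_sv=3.0)
        genes, svs, tes, ppi, gene_iv = synth_gene_annotations(cfg)
        loss = genes["n_alleles"] < 4
        flag = genes["sv_flag"]
        a = int((loss & flag).sum())
        b = int((loss & ~flag).sum())
        c = int((~loss & flag).sum())
        d = int((~loss & ~flag).sum())
        res = gs.fisher_enrichment(a, b, c, d)
        assert 2.0 <= res.odds_ratio <= 4.5

    def test_interval_classification_recovers_flags(self):
        cfg = SynthConfig(seed=6, n_genes=400, or_sv=2.0)
        genes, svs, tes, ppi, gene_iv = synth_gene_annotations(cfg)
        cls = gs.classify_gene_sv(gene_iv, svs, margin_bp=2000)
        flagged = cls.isin(["within_sv", "near_sv"])
        assert (flagged.to_numpy() == genes["sv_flag"].to_numpy()).all()
        te = gs.flag_te_overlap(gene_iv, tes)
        assert (te.to_numpy() == genes["te_overlap"].to_numpy()).all()
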