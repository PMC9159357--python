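"""Sequence features, R^2 ranking and hexamer enrichment."""

import numpy as np
import pandas as pd
import pytest

from apastab import sim
from apastab._seq import base_fractions, gc_fraction, u_fraction
from apastab.apa import select_pairs
from apastab.features import (
    compute_features,
    count_hexamers,
    hexamer_enrichment,
    region_sequence,
    regression_rank,
)


class TestContent:
    def test_pure_gc_region(self):
        assert gc_fraction("GCGC") == 1.0
        assert u_fraction("GCGC") == 0.0

    def test_minus_strand_content_is_sense_strand(self):
        ref = {"chr1": "AAAA"}
        seq = region_sequence(ref, "chr1", 0, 4, "-")
        assert seq == "TTTT"
        assert u_fraction(seq) == 1.0

    def test_base_fractions_sum_to_one(self):
        fr = base_fractions("ACGTACGTGG")
        assert sum(fr.values()) == pytest.approx(1.0)

    def test_region_outside_reference_is_an_error(self):
        with pytest.raises(ValueError):
            region_sequence({"chr1": "ACGT"}, "chr1", 0, 10, "+")


@pytest.fixture(scope="module")
def feats(small_exp, small_norm):
    counts = small_norm["counts"]
    truth = small_exp["truth"]
    meta = pd.DataFrame(
        {
            "chrom": truth.loc[counts.index, "chrom"],
            "strand": truth.loc[counts.index, "strand"],
            "summit": truth.loc[counts.index, "pas_pos"].astype(int),
            "gene_id": truth.loc[counts.index, "gene_id"],
            "region_class": truth.loc[counts.index, "region_class"],
        }
    )
    pairs = select_pairs(meta, counts, small_exp["samples"])
    return compute_features(
        small_exp["annotation"], small_exp["reference"], pairs=pairs,
        clusters=meta,
    )


class TestComputeFeatures:
    def test_content_fractions_are_valid(self, feats):
        for col in ("gene_GC", "gene_U", "utr3_GC", "utr3_U"):
            v = feats[col].dropna()
            assert ((v >= 0) & (v <= 1)).all()

    def test_two_exon_genes_have_positive_junction_density(self, feats, small_exp):
        for g in small_exp["annotation"]:
            assert feats.loc[g.gene_id, "junction_density"] > 0

    def test_autr_features_only_for_paired_genes(self, feats):
        with_pair = feats["aUTR_size"].notna()
        assert with_pair.any()
        assert (feats.loc[with_pair, "aUTR_GC"].between(0, 1)).all()

    def test_single_exon_gene_has_zero_junction_density(self, small_exp):
        from apastab.annotation import Gene, GenomeAnnotation

        g = Gene("G", "chr1", "+", 0, 100, exons=[(0, 100)], pas_positions=[90],
                 utr3_anchor=50)
        ann = GenomeAnnotation({"chr1": 200}, [g])
        ref = {"chr1": "ACGT" * 50}
        f = compute_features(ann, ref)
        assert f.loc["G", "junction_density"] == 0.0


class TestRegressionRank:
    def test_perfect_single_feature_ranked_first(self):
        rng = np.random.default_rng(0)
        x1 = rng.normal(size=200)
        x2 = rng.normal(size=200)
        feats = pd.DataFrame({"x1": x1, "x2": x2})
        report = regression_rank(feats, pd.Series(2.0 * x1))
        assert report.index[0] == "x1"
        assert report.loc["x1", "r2_individual"] == pytest.approx(1.0)
        assert report.loc["x1", "sign"] == 1.0

    def test_cumulative_r2_is_non_decreasing(self):
        rng = np.random.default_rng(1)
        feats = pd.DataFrame(rng.normal(size=(300, 5)), columns=list("abcde"))
        y = feats["a"] - 0.5 * feats["b"] + rng.normal(size=300)
        report = regression_rank(feats, y)
        assert (np.diff(report["r2_cumulative"]) >= -1e-12).all()

    def test_affine_feature_rescaling_leaves_r2_unchanged(self):
        rng = np.random.default_rng(2)
        feats = pd.DataFrame(rng.normal(size=(200, 3)), columns=list("abc"))
        y = feats["a"] + rng.normal(size=200)
        r1 = regression_rank(feats, y)
        feats2 = feats.copy()
        feats2["a"] = 100.0 * feats2["a"] + 7.0
        r2 = regression_rank(feats2, y)
        np.testing.assert_allclose(
            r1["r2_individual"], r2["r2_individual"], atol=1e-9
        )
        np.testing.assert_allclose(
            r1["r2_cumulative"], r2["r2_cumulative"], atol=1e-9
        )

    def test_constant_feature_gets_zero_r2(self):
        rng = np.random.default_rng(3)
        feats = pd.DataFrame(
            {"x": rng.normal(size=100), "const": np.ones(100)}
        )
        report = regression_rank(feats, pd.Series(rng.normal(size=100)))
        assert report.loc["const", "r2_individual"] == 0.0

    def test_too_few_observations_rejected(self):
        feats = pd.DataFrame({"a": [1.0, 2.0], "b": [2.0, 1.0]})
        with pytest.raises(ValueError):
            regression_rank(feats, pd.Series([1.0, 2.0]))


class TestHexamers:
    def test_overlapping_occurrence_counting(self):
        counts = count_hexamers(["GCGCGCGC"])
        assert counts["GCGCGC"] == 2
        assert counts["CGCGCG"] == 1
        assert counts.sum() == 3

    def test_identical_sets_show_no_enrichment(self):
        seqs = ["ACGTACGTACGTACGT", "GGCCTTAAGGCCTTAA"]
        table, pfm = hexamer_enrichment(seqs, seqs)
        present = table[table["fg_count"] > 0]
        np.testing.assert_allclose(present["odds_ratio"], 1.0)
        assert table["q"].min() == pytest.approx(1.0)
        assert pfm.sum() == 0.0

    def test_planted_motif_recovered(self):
        rng = np.random.default_rng(7)

        def random_seq(n):
            return "".join(rng.choice(list("ACGT"), size=n))

        bg = [random_seq(100) for _ in range(200)]
        fg = []
        for i in range(200):
            s = random_seq(100)
            if i % 2 == 0:
                s = s[:40] + "TGTGTG" + s[46:]
            fg.append(s)
        table, pfm = hexamer_enrichment(fg, bg)
        assert table.loc["TGTGTG", "q"] < 0.05
        assert table.loc["TGTGTG", "odds_ratio"] > 1
        top = table[(table["odds_ratio"] > 1) & (table["q"] < 0.05)]
        assert "TGTGTG" in set(top.sort_values("q").index[:10])
        # position-frequency matrix is column-normalized over used hexamers
        np.testing.assert_allclose(pfm.sum(axis=0), 1.0)

    def test_empty_set_is_an_error(self):
        with pytest.raises(ValueError):
            hexamer_enrichment([], ["ACGTAC"])

    def test_small_count_fisher_matches_enumeration(self):
        from apastab.benchmarks import fisher_oracle_two_sided
        from scipy import stats

        table = [[3, 17], [9, 11]]
        _, p = stats.fisher_exact(table, alternative="two-sided")
        assert p == pytest.approx(fisher_oracle_two_sided(table), abs=1e-12)
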