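"""APA isoform-pair selection, RE/RED, usage/stability tests, binning."""

import numpy as np
import pandas as pd
import pytest

from apastab import apa
from apastab.benchmarks import fisher_oracle_two_sided


def tpa_meta(summits, strand="+"):
    return pd.DataFrame(
        {
            "summit": summits,
            "strand": strand,
            "gene_id": "G1",
            "region_class": "TPA",
        },
        index=[f"c{i}" for i in range(len(summits))],
    )


class TestSelectIsoformPair:
    def test_top_two_by_expression_ordered_by_position(self):
        meta = tpa_meta([1000, 1500, 2000])
        expr = pd.Series({"c0": 100, "c1": 5, "c2": 90})
        assert apa.select_isoform_pair(meta, expr) == ("c0", "c2")

    def test_single_pas_gives_none(self):
        assert apa.select_isoform_pair(tpa_meta([100]), pd.Series({"c0": 9})) is None

    def test_expression_tie_prefers_proximal(self):
        meta = tpa_meta([1000, 1500, 2000])
        expr = pd.Series({"c0": 50, "c1": 50, "c2": 50})
        assert apa.select_isoform_pair(meta, expr) == ("c0", "c1")

    def test_minus_strand_proximal_is_higher_coordinate(self):
        meta = tpa_meta([1000, 2000], strand="-")
        expr = pd.Series({"c0": 10, "c1": 10})
        # proximal on '-' is the larger coordinate
        assert apa.select_isoform_pair(meta, expr) == ("c1", "c0")


class TestRelativeExpression:
    def test_quarter_ratio_gives_minus_two(self):
        assert apa.relative_expression(4, 16, pseudocount=0) == pytest.approx(-2.0)

    def test_red_antisymmetry(self):
        assert apa.red(1.25, -0.5) == pytest.approx(1.75)
        assert apa.red(0.3, 0.9) == -apa.red(0.9, 0.3)


class TestUsageTest:
    def test_balanced_table_makes_no_call(self):
        p, diff, call = apa.apa_usage_test((50, 50), (50, 50))
        assert p == pytest.approx(1.0)
        assert diff == pytest.approx(0.0)
        assert call is None

    def test_small_table_matches_hypergeometric_enumeration(self):
        p, _, call = apa.apa_usage_test((3, 1), (1, 3))
        assert p == pytest.approx(0.485714285714, abs=1e-9)
        assert p == pytest.approx(fisher_oracle_two_sided([[3, 1], [1, 3]]))
        assert call is None

    def test_strong_shift_called_lengthened(self):
        p, diff, call = apa.apa_usage_test((900, 500), (100, 500))
        assert p < 1e-10
        assert diff == pytest.approx(0.40)
        assert call == "lengthened"

    def test_all_zero_table_makes_no_call(self):
        p, diff, call = apa.apa_usage_test((0, 0), (0, 0))
        assert np.isnan(p) and call is None

    def test_direction_flips_with_sample_order(self):
        _, d1, c1 = apa.apa_usage_test((900, 500), (100, 500))
        _, d2, c2 = apa.apa_usage_test((500, 900), (500, 100))
        assert d1 == pytest.approx(-d2)
        assert (c1, c2) == ("lengthened", "shortened")


class TestIsoformStabilityTest:
    def test_equal_proportions_give_p_one_and_zero_dss(self):
        dss, p = apa.isoform_stability_test(100, 100, 50, 50)
        assert p == pytest.approx(1.0)
        assert dss == pytest.approx(0.0)

    def test_ft_enriched_distal_is_red_direction(self):
        # [pPAS, dPAS] x [4sU, FT]: dPAS relatively enriched in FT
        dss, p = apa.isoform_stability_test(200, 100, 50, 100)
        assert dss > 0 and p < 0.05

    def test_zero_isoform_makes_no_call(self):
        dss, p = apa.isoform_stability_test(0, 0, 10, 10)
        assert np.isnan(dss) and np.isnan(p)


class TestQuintileBins:
    def test_ten_values_give_five_bins_of_two(self):
        values = pd.Series(np.arange(10, dtype=float))
        ba = apa.quintile_bins(values)
        sizes = ba.assignment.value_counts()
        assert sorted(sizes) == [2, 2, 2, 2, 2]
        assert ba.bin_ranges[0] == (0.0, 1.0)
        assert ba.bin_ranges[-1] == (8.0, 9.0)

    def test_binning_is_permutation_invariant(self):
        rng = np.random.default_rng(0)
        values = pd.Series(rng.normal(size=23))
        shuffled = values.sample(frac=1.0, random_state=1)
        b1 = apa.quintile_bins(values)
        b2 = apa.quintile_bins(shuffled)
        assert b1.assignment.sort_index().equals(b2.assignment.sort_index())

    def test_bin_sizes_differ_by_at_most_one(self):
        ba = apa.quintile_bins(pd.Series(np.arange(23, dtype=float)))
        sizes = ba.assignment.value_counts()
        assert sizes.max() - sizes.min() <= 1

    def test_fewer_than_five_values_is_an_error(self):
        with pytest.raises(ValueError):
            apa.quintile_bins(pd.Series([1.0, 2.0, 3.0, 4.0]))

    def test_response_gradient_detected_between_extreme_bins(self):
        rng = np.random.default_rng(3)
        x = pd.Series(rng.uniform(0, 1, size=200))
        y = -2.0 * x + pd.Series(rng.normal(0, 0.3, size=200))
        ba = apa.quintile_bins(x, y, variable="x")
        assert ba.comparison.pvalue < 0.01


class TestIpaAnalysis:
    def test_no_ipa_clusters_gives_empty_result(self):
        meta = tpa_meta([100, 200])
        counts = pd.DataFrame(
            {"s1": [10, 10]}, index=meta.index
        )
        samples = pd.DataFrame(
            {"condition": ["lineA"], "fraction": ["total"], "replicate": [1]},
            index=["s1"],
        )
        events, bins = apa.ipa_analysis(meta, counts, counts, samples)
        assert len(events) == 0 and bins == {}
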