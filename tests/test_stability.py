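"""Stability scores, ANOVA screen and group comparisons."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from apastab import sim
from apastab.benchmarks import ranksum_oracle_two_sided
from apastab.stability import (
    anova_differential,
    delta_ss,
    group_compare,
    stability_score,
    stability_table,
)


class TestStabilityScore:
    def test_four_fold_ratio_gives_two(self):
        assert stability_score(8, 2, pseudocount=0) == pytest.approx(2.0)

    def test_equal_pools_give_zero(self):
        assert stability_score(5.5, 5.5, pseudocount=0) == pytest.approx(0.0)

    def test_noiseless_kinetics_reproduce_closed_form(self):
        _, labeled, unlabeled = sim.expected_fractions(3.0, 2 * math.log(2), 1.0)
        ss = stability_score(unlabeled, labeled, pseudocount=0)
        assert ss == pytest.approx(-1.5849625007, abs=1e-9)

    def test_double_zero_without_pseudocount_is_missing(self):
        assert math.isnan(stability_score(0.0, 0.0, pseudocount=0))

    def test_negative_abundance_rejected(self):
        with pytest.raises(ValueError):
            stability_score(-1.0, 2.0)

    def test_monotone_decreasing_in_decay_rate(self):
        ks = np.logspace(-2, 1, 30)
        _, lab, unlab = sim.expected_fractions(1.0, ks, 1.0)
        ss = stability_score(unlab, lab, pseudocount=0)
        assert np.all(np.diff(ss) < 0)


def textbook_anova(groups):
    """Second, textbook-formula route: SSB/(g-1) over SSW/(N-g)."""
    means = [np.mean(g) for g in groups]
    grand = np.mean(np.concatenate(groups))
    ssb = sum(len(g) * (m - grand) ** 2 for g, m in zip(groups, means))
    ssw = sum(sum((x - m) ** 2 for x in g) for g, m in zip(groups, means))
    df1, df2 = len(groups) - 1, sum(len(g) for g in groups) - len(groups)
    f = (ssb / df1) / (ssw / df2)
    return f, float(sps.f.sf(f, df1, df2))


class TestAnova:
    def test_hand_computed_three_group_case(self):
        f, p = anova_differential([[0, 1], [1, 2], [2, 3]])
        assert f == pytest.approx(4.0)
        assert p == pytest.approx(float(sps.f.sf(4.0, 2, 3)))

    def test_all_equal_values_give_f_zero_p_one(self):
        assert anova_differential([[1, 1], [1, 1]]) == (0.0, 1.0)

    def test_zero_within_variance_with_spread_is_certain(self):
        f, p = anova_differential([[1, 1], [2, 2]])
        assert math.isinf(f) and p == 0.0

    def test_matches_textbook_formula_on_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            groups = [
                rng.normal(size=rng.integers(2, 6)).tolist()
                for _ in range(rng.integers(2, 5))
            ]
            f1, p1 = anova_differential(groups)
            f2, p2 = textbook_anova(groups)
            assert f1 == pytest.approx(f2, abs=1e-9)
            assert p1 == pytest.approx(p2, abs=1e-9)

    def test_single_replicate_rejected(self):
        with pytest.raises(ValueError):
            anova_differential([[1], [2]])


class TestDeltaSS:
    def test_difference_and_antisymmetry(self):
        assert delta_ss(2.0, 0.5) == pytest.approx(1.5)
        assert delta_ss(0.3, 1.9) == -delta_ss(1.9, 0.3)
        assert delta_ss(1.1, 1.1) == 0.0
        assert math.isnan(float(delta_ss(np.nan, 1.0)))


class TestGroupCompare:
    def test_identical_groups_not_significant(self):
        r = group_compare([1, 2, 3, 4], [1, 2, 3, 4])
        assert r.pvalue > 0.5

    def test_complete_separation_is_significant(self):
        r = group_compare(list(range(1, 21)), list(range(101, 121)))
        assert r.pvalue < 0.001

    def test_empty_group_is_an_error(self):
        with pytest.raises(ValueError):
            group_compare([], [1.0])

    def test_unknown_test_rejected(self):
        with pytest.raises(ValueError):
            group_compare([1], [2], test="t_test")

    def test_small_sample_ranksum_matches_permutation_enumeration(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            n1, n2 = int(rng.integers(2, 8)), int(rng.integers(2, 8))
            vals = rng.choice(500, size=n1 + n2, replace=False).astype(float)
            a, b = vals[:n1].tolist(), vals[n1:].tolist()
            got = group_compare(a, b, "wilcoxon_ranksum").pvalue
            want = ranksum_oracle_two_sided(a, b)
            assert got == pytest.approx(want, abs=1e-12)

    def test_ks_two_sample_runs(self):
        r = group_compare([1, 2, 3], [4, 5, 6], "ks_two_sample")
        assert 0 <= r.pvalue <= 1


class TestStabilityTable:
    def test_condition_mean_is_replicate_mean(self, small_exp, small_norm):
        ss = stability_table(small_norm["norm"], small_exp["samples"])
        for cond in ("lineA", "lineB", "lineC"):
            reps = [c for c in ss.columns if c.startswith(f"SS_{cond}_rep")]
            np.testing.assert_allclose(
                ss[f"SS_{cond}"], ss[reps].mean(axis=1)
            )

    def test_replicate_averaging_is_permutation_invariant(self, small_exp, small_norm):
        samples = small_exp["samples"].copy()
        # swap replicate labels within each condition x fraction
        samples["replicate"] = samples["replicate"].map({1: 2, 2: 1})
        ss1 = stability_table(small_norm["norm"], small_exp["samples"])
        ss2 = stability_table(small_norm["norm"], samples)
        np.testing.assert_allclose(ss1["SS_lineA"], ss2["SS_lineA"])
        np.testing.assert_allclose(ss1["anova_F"], ss2["anova_F"])

    def test_anova_columns_present_with_valid_q(self, small_exp, small_norm):
        ss = stability_table(small_norm["norm"], small_exp["samples"])
        assert {"anova_F", "anova_p", "anova_q"} <= set(ss.columns)
        ok = ss["anova_q"].dropna()
        assert ((ok >= 0) & (ok <= 1)).all()
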