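"""Stability scores and differential-stability statistics.

The stability score of a transcript (represented by its PAS) is
SS = log2(FT RPM / 4sU RPM): the pre-existing over the newly made pool.
Higher SS means more stable.  Replicates are averaged after computing
per-replicate SS; differential stability across conditions is tested by
one-way ANOVA, with BH-adjusted q-values reported alongside raw p.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


def stability_score(ft_rpm, fsu_rpm, pseudocount: float = 1.0):
    """SS = log2((FT + pc) / (4sU + pc)); NaN where undefined (pc = 0
    and a zero abundance makes the ratio 0/0, 0 or infinite)."""
    ft = np.asarray(ft_rpm, dtype=float)
    su = np.asarray(fsu_rpm, dtype=float)
    if np.any(ft < 0) or np.any(su < 0):
        raise ValueError("abundances must be >= 0")
    num = ft + pseudocount
    den = su + pseudocount
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.log2(num) - np.log2(den)
    out = np.where((num == 0) | (den == 0), np.nan, out)
    return out if out.shape else float(out)


def delta_ss(ss_a, ss_b):
    """Antisymmetric stability-score difference (NaN propagates)."""
    return np.asarray(ss_a, dtype=float) - np.asarray(ss_b, dtype=float)


def anova_differential(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """One-way fixed-effects ANOVA across conditions.

    Returns (F, p) with df (g-1, N-g).  All-equal input (zero between-
    and within-group variance) returns (0.0, 1.0) by convention; zero
    within-group variance with real between-group spread returns
    (inf, 0.0).
    """
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if len(arrs) < 2 or any(len(a) < 2 for a in arrs):
        raise ValueError("need >= 2 conditions with >= 2 replicates each")
    allv = np.concatenate(arrs)
    grand = allv.mean()
    ssb = sum(len(a) * (a.mean() - grand) ** 2 for a in arrs)
    ssw = sum(((a - a.mean()) ** 2).sum() for a in arrs)
    if ssw == 0.0:
        if ssb == 0.0:
            return 0.0, 1.0
        return math.inf, 0.0
    f, p = stats.f_oneway(*arrs)
    return float(f), float(p)


@dataclass
class GroupComparison:
    """A two-group (or multi-group) distribution comparison."""

    test: str
    statistic: float
    pvalue: float


def group_compare(
    values_a: Sequence[float],
    values_b: Sequence[float],
    test: str = "wilcoxon_ranksum",
) -> GroupComparison:
    """Two-sided two-group comparison by the named test.

    ``wilcoxon_ranksum`` uses the exact Mann-Whitney null distribution
    for small untied samples, matching full permutation enumeration.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty group")
    if test == "wilcoxon_ranksum":
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
    elif test == "ks_two_sample":
        res = stats.ks_2samp(a, b)
    elif test == "anova_oneway":
        res = stats.f_oneway(a, b)
    elif test == "fisher_exact":
        table = np.array([a, b], dtype=int)
        odds, p = stats.fisher_exact(table, alternative="two-sided")
        return GroupComparison(test=test, statistic=float(odds), pvalue=float(p))
    else:
        raise ValueError(f"unknown test {test!r}")
    return GroupComparison(
        test=test, statistic=float(res.statistic), pvalue=float(res.pvalue)
    )


def stability_table(
    rpm: pd.DataFrame,
    samples: pd.DataFrame,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Per-PAS stability scores with the cross-condition ANOVA.

    Computes SS per (condition, replicate) from matched FT and 4sU
    libraries, averages replicates per condition, and tests differential
    stability across conditions by one-way ANOVA on replicate SS.
    Columns: ``SS_<cond>_rep<r>``, ``SS_<cond>``, ``anova_F``,
    ``anova_p``, ``anova_q``.
    """
    conditions = list(dict.fromkeys(samples["condition"]))
    out = pd.DataFrame(index=rpm.index)
    rep_cols: dict[str, list[str]] = {c: [] for c in conditions}
    for cond in conditions:
        sub = samples[samples["condition"] == cond]
        reps = sorted(sub["replicate"].unique())
        for rep in reps:
            ft = sub[(sub["fraction"] == "FT") & (sub["replicate"] == rep)]
            su = sub[(sub["fraction"] == "4sU") & (sub["replicate"] == rep)]
            if len(ft) != 1 or len(su) != 1:
                raise ValueError(
                    f"condition {cond} replicate {rep}: need exactly one FT "
                    "and one 4sU library"
                )
            col = f"SS_{cond}_rep{rep}"
            out[col] = stability_score(
                rpm[ft.index[0]], rpm[su.index[0]], pseudocount
            )
            rep_cols[cond].append(col)
        out[f"SS_{cond}"] = out[rep_cols[cond]].mean(axis=1)

    if len(conditions) >= 2 and all(len(v) >= 2 for v in rep_cols.values()):
        fvals = np.empty(len(out))
        pvals = np.empty(len(out))
        groups_mat = [out[rep_cols[c]].to_numpy() for c in conditions]
        for i in range(len(out)):
            groups = [g[i] for g in groups_mat]
            if any(np.isnan(g).any() for g in groups):
                fvals[i], pvals[i] = np.nan, np.nan
            else:
                fvals[i], pvals[i] = anova_differential(groups)
        out["anova_F"] = fvals
        out["anova_p"] = pvals
        ok = ~np.isnan(pvals)
        q = np.full(len(out), np.nan)
        if ok.any():
            q[ok] = multipletests(pvals[ok], method="fdr_bh")[1]
        out["anova_q"] = q
    return out
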