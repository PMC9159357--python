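"""Alternative-polyadenylation isoform analytics.

For each gene the two most expressed 3'-most-exon (TPA) isoforms are
selected and labeled proximal (pPAS) / distal (dPAS) by strand-aware
genomic order.  Relative expression RE = log2(dPAS/pPAS) describes
3'UTR-length preference per sample; RED (RE difference between two
samples or conditions) describes lengthening (positive) or shortening.
Isoform stability differences use the 2x2 exact-test route
([pPAS, dPAS] x [4sU, FT], replicates pooled, BH FDR), with the sign of
dSS = SS(dPAS) - SS(pPAS) giving direction.  Intronic-polyadenylation
(IPA) isoforms are compared against the terminal-exon (TPA) isoform the
same way, and binned by host-intron size and splice-site strength.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .stability import GroupComparison, group_compare, stability_score

DEFAULT_ALPHA = 0.05
DEFAULT_REL_ABUND = 0.05


def relative_expression(d_rpm, p_rpm, pseudocount: float = 1.0):
    """RE = log2((dPAS + pc) / (pPAS + pc))."""
    d = np.asarray(d_rpm, dtype=float)
    p = np.asarray(p_rpm, dtype=float)
    if np.any(d < 0) or np.any(p < 0):
        raise ValueError("abundances must be >= 0")
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.log2(d + pseudocount) - np.log2(p + pseudocount)
    return out if out.shape else float(out)


def red(re_a, re_b):
    """RE difference between two samples/conditions (antisymmetric)."""
    return np.asarray(re_a, dtype=float) - np.asarray(re_b, dtype=float)


def select_isoform_pair(
    tpa_meta: pd.DataFrame, expression: pd.Series
) -> Optional[tuple[str, str]]:
    """Pick a gene's (pPAS, dPAS) cluster ids, or None.

    ``tpa_meta`` holds the gene's TPA clusters (columns ``summit``,
    ``strand``); ``expression`` the selection basis (summed expression
    across conditions).  The two most expressed clusters are taken (ties
    resolved toward the more proximal site) and ordered proximal/distal
    along the transcript strand.
    """
    if len(tpa_meta) < 2:
        return None
    strand = tpa_meta["strand"].iloc[0]
    # proximal = lower summit on '+', higher on '-'
    prox_key = tpa_meta["summit"] if strand == "+" else -tpa_meta["summit"]
    order = pd.DataFrame(
        {"expr": expression.reindex(tpa_meta.index).fillna(0.0), "prox": prox_key}
    ).sort_values(["expr", "prox"], ascending=[False, True])
    top2 = order.index[:2]
    a, b = top2[0], top2[1]
    sa, sb = tpa_meta.loc[a, "summit"], tpa_meta.loc[b, "summit"]
    if (strand == "+") == (sa < sb):
        return a, b
    return b, a


def apa_usage_test(
    p_counts: Sequence[int],
    d_counts: Sequence[int],
    alpha: float = DEFAULT_ALPHA,
    min_rel_diff: float = DEFAULT_REL_ABUND,
) -> tuple[float, float, Optional[str]]:
    """Isoform-usage shift between two samples.

    2x2 Fisher exact on [pPAS, dPAS] x [sample1, sample2] raw counts.
    Relative abundance of the dPAS isoform is d/(p+d) per sample; the
    event is called ``lengthened`` (in sample 2) or ``shortened`` when
    p < alpha and the absolute relative-abundance difference exceeds
    ``min_rel_diff``.  Returns (p, rel-abundance difference, call).
    """
    p1, p2 = (int(x) for x in p_counts)
    d1, d2 = (int(x) for x in d_counts)
    if p1 + p2 + d1 + d2 == 0:
        return float("nan"), float("nan"), None
    _, pval = stats.fisher_exact([[p1, p2], [d1, d2]], alternative="two-sided")
    rel1 = d1 / (p1 + d1) if (p1 + d1) else np.nan
    rel2 = d2 / (p2 + d2) if (p2 + d2) else np.nan
    diff = rel2 - rel1
    call = None
    if pval < alpha and np.isfinite(diff) and abs(diff) > min_rel_diff:
        call = "lengthened" if diff > 0 else "shortened"
    return float(pval), float(diff), call


def isoform_stability_test(
    p_4su: int,
    p_ft: int,
    d_4su: int,
    d_ft: int,
    pseudocount: float = 1.0,
) -> tuple[float, float]:
    """Stability difference between a gene's two isoforms in one condition.

    Fisher exact on [pPAS, dPAS] x [4sU, FT] pooled replicate counts;
    dSS = SS(dPAS) - SS(pPAS) computed on the same pooled counts gives
    the direction (positive: dPAS more stable).  Returns (dSS, p).
    """
    if (p_4su + p_ft == 0) or (d_4su + d_ft == 0):
        return float("nan"), float("nan")
    _, pval = stats.fisher_exact(
        [[p_4su, p_ft], [d_4su, d_ft]], alternative="two-sided"
    )
    dss = stability_score(d_ft, d_4su, pseudocount) - stability_score(
        p_ft, p_4su, pseudocount
    )
    return float(dss), float(pval)


@dataclass
class BinAnalysis:
    """Equal-size bins of a variable with a bin1-vs-bin5 comparison."""

    variable: str
    n_bins: int
    assignment: pd.Series  # 1..n_bins per item, ordered by the variable
    bin_ranges: list[tuple[float, float]]
    comparison: GroupComparison  # response in bin 1 vs bin n


def quintile_bins(
    values: pd.Series,
    response: Optional[pd.Series] = None,
    n_bins: int = 5,
    variable: str = "value",
) -> BinAnalysis:
    """Rank-split items into ``n_bins`` (near-)equal bins by ``values``.

    Bin sizes differ by at most one; ties are broken by stable input
    order.  The ``response`` distribution (default: the binning values
    themselves) in the first and last bins is compared by rank-sum test.
    """
    vals = values.dropna()
    if len(vals) < n_bins:
        raise ValueError(f"need at least {n_bins} finite values")
    if response is None:
        response = values
    order = vals.index[np.argsort(vals.to_numpy(), kind="stable")]
    chunks = np.array_split(np.arange(len(order)), n_bins)
    assignment = pd.Series(index=vals.index, dtype=int)
    ranges = []
    groups = []
    for b, chunk in enumerate(chunks, start=1):
        idx = order[chunk]
        assignment[idx] = b
        vv = vals.loc[idx]
        ranges.append((float(vv.min()), float(vv.max())))
        groups.append(response.loc[idx].dropna().to_numpy())
    comp = group_compare(groups[0], groups[-1], "wilcoxon_ranksum")
    return BinAnalysis(
        variable=variable,
        n_bins=n_bins,
        assignment=assignment,
        bin_ranges=ranges,
        comparison=comp,
    )


# ---------------------------------------------------------------------------
# gene-level tables


def select_pairs(
    meta: pd.DataFrame, counts: pd.DataFrame, samples: pd.DataFrame
) -> pd.DataFrame:
    """Top-two 3'UTR isoform pair per gene with >= 2 expressed TPA PASs.

    Selection basis is combined expression across all conditions in the
    total fraction.  Returns one row per gene: pPAS/dPAS cluster ids,
    summits and aUTR size (genomic distance between the two summits).
    """
    total_cols = samples.index[samples["fraction"] == "total"]
    total_cols = [c for c in total_cols if c in counts.columns]
    basis = counts[total_cols].sum(axis=1) if total_cols else counts.sum(axis=1)
    rows = []
    tpa = meta[meta["region_class"] == "TPA"]
    for gene_id, grp in tpa.groupby("gene_id", sort=True):
        if gene_id is None:
            continue
        pair = select_isoform_pair(grp, basis)
        if pair is None:
            continue
        p_id, d_id = pair
        rows.append(
            {
                "gene_id": gene_id,
                "p_id": p_id,
                "d_id": d_id,
                "strand": grp["strand"].iloc[0],
                "p_summit": int(grp.loc[p_id, "summit"]),
                "d_summit": int(grp.loc[d_id, "summit"]),
                "autr_size": int(abs(grp.loc[d_id, "summit"] - grp.loc[p_id, "summit"])),
            }
        )
    return pd.DataFrame(rows).set_index("gene_id") if rows else pd.DataFrame(
        columns=["p_id", "d_id", "strand", "p_summit", "d_summit", "autr_size"]
    )


def _pooled(counts: pd.DataFrame, samples: pd.DataFrame, cond: str, frac: str):
    cols = samples.index[
        (samples["condition"] == cond) & (samples["fraction"] == frac)
    ]
    cols = [c for c in cols if c in counts.columns]
    return counts[cols].sum(axis=1)


def pair_stability_table(
    pairs: pd.DataFrame,
    counts: pd.DataFrame,
    rpm: pd.DataFrame,
    samples: pd.DataFrame,
    pseudocount: float = 1.0,
    alpha_fdr: float = 0.05,
) -> pd.DataFrame:
    """Per-gene isoform stability comparison in every condition.

    For each condition: pooled-count Fisher exact ([pPAS, dPAS] x
    [4sU, FT]) with BH FDR across genes; dSS_<cond> = SS(dPAS) -
    SS(pPAS) from replicate-averaged RPM; call ``red`` (dPAS more
    stable) / ``blue`` (pPAS more stable) at FDR < ``alpha_fdr``.
    Also reports RE_<cond>_<fraction> from pooled RPM.
    """
    conditions = list(dict.fromkeys(samples["condition"]))
    out = pairs.copy()
    for cond in conditions:
        su = _pooled(counts, samples, cond, "4sU")
        ft = _pooled(counts, samples, cond, "FT")
        dss = np.empty(len(pairs))
        pv = np.empty(len(pairs))
        for i, (_, row) in enumerate(pairs.iterrows()):
            dss[i], pv[i] = isoform_stability_test(
                int(su[row["p_id"]]), int(ft[row["p_id"]]),
                int(su[row["d_id"]]), int(ft[row["d_id"]]),
                pseudocount,
            )
        # direction from replicate-averaged RPM-based SS when available
        su_rpm = _pooled(rpm, samples, cond, "4sU")
        ft_rpm = _pooled(rpm, samples, cond, "FT")
        n_rep = max(
            1,
            len(
                samples[(samples["condition"] == cond) & (samples["fraction"] == "4sU")]
            ),
        )
        su_rpm, ft_rpm = su_rpm / n_rep, ft_rpm / n_rep
        ss_d = stability_score(
            ft_rpm[pairs["d_id"]].to_numpy(), su_rpm[pairs["d_id"]].to_numpy(), pseudocount
        )
        ss_p = stability_score(
            ft_rpm[pairs["p_id"]].to_numpy(), su_rpm[pairs["p_id"]].to_numpy(), pseudocount
        )
        out[f"dSS_{cond}"] = ss_d - ss_p
        out[f"stab_p_{cond}"] = pv
        ok = np.isfinite(pv)
        q = np.full(len(pairs), np.nan)
        if ok.any():
            q[ok] = multipletests(pv[ok], method="fdr_bh")[1]
        out[f"stab_q_{cond}"] = q
        call = np.where(
            (q < alpha_fdr) & (out[f"dSS_{cond}"] > 0),
            "red",
            np.where((q < alpha_fdr) & (out[f"dSS_{cond}"] < 0), "blue", "ns"),
        )
        out[f"stab_call_{cond}"] = call
        for frac in ("total", "4sU", "FT"):
            fr = _pooled(rpm, samples, cond, frac)
            nr = max(
                1,
                len(
                    samples[
                        (samples["condition"] == cond) & (samples["fraction"] == frac)
                    ]
                ),
            )
            fr = fr / nr
            out[f"RE_{cond}_{frac}"] = relative_expression(
                fr[pairs["d_id"]].to_numpy(), fr[pairs["p_id"]].to_numpy(), pseudocount
            )
    return out


def blue_red_ratio(pair_table: pd.DataFrame, condition: str) -> tuple[int, int, float]:
    """(n_blue, n_red, blue/red ratio) for one condition's calls."""
    calls = pair_table[f"stab_call_{condition}"]
    n_blue = int((calls == "blue").sum())
    n_red = int((calls == "red").sum())
    ratio = n_blue / n_red if n_red else float("inf")
    return n_blue, n_red, ratio


def usage_shift_table(
    pairs: pd.DataFrame,
    counts: pd.DataFrame,
    samples: pd.DataFrame,
    cond_a: str,
    cond_b: str,
    alpha: float = DEFAULT_ALPHA,
    min_rel_diff: float = DEFAULT_REL_ABUND,
) -> pd.DataFrame:
    """Per-gene 3'UTR usage shift between two conditions.

    Fisher exact on pooled total-fraction counts; BH FDR reported across
    genes; call ``lengthened``/``shortened`` in ``cond_b`` relative to
    ``cond_a``.
    """
    ta = _pooled(counts, samples, cond_a, "total")
    tb = _pooled(counts, samples, cond_b, "total")
    rows = []
    for gene_id, row in pairs.iterrows():
        pv, diff, call = apa_usage_test(
            (int(ta[row["p_id"]]), int(tb[row["p_id"]])),
            (int(ta[row["d_id"]]), int(tb[row["d_id"]])),
            alpha,
            min_rel_diff,
        )
        rows.append(
            {"gene_id": gene_id, "usage_p": pv, "rel_abund_diff": diff, "call": call}
        )
    out = pd.DataFrame(rows).set_index("gene_id")
    ok = np.isfinite(out["usage_p"])
    q = np.full(len(out), np.nan)
    if ok.any():
        q[ok.to_numpy()] = multipletests(out.loc[ok, "usage_p"], method="fdr_bh")[1]
    out["usage_q"] = q
    return out


def ipa_analysis(
    meta: pd.DataFrame,
    counts: pd.DataFrame,
    rpm: pd.DataFrame,
    samples: pd.DataFrame,
    annotation=None,
    pseudocount: float = 1.0,
    tpa_ref: str = "top",
) -> tuple[pd.DataFrame, dict[str, dict[str, BinAnalysis]]]:
    """Intronic-polyadenylation isoforms vs the terminal-exon isoform.

    For each gene with >= 1 IPA and >= 1 TPA cluster, the reference TPA
    isoform is the most abundant TPA cluster (``tpa_ref='top'``) or the
    per-sample sum of TPA clusters (``'sum'``).  Per condition, reports
    dSS_<cond> = SS(IPA) - SS(TPA) and relative abundance
    log2(IPA/TPA) from pooled total RPM.  Returns the event table and
    per-condition quintile-bin analyses of SS(IPA) by host-intron size
    and splice-site strengths (skipped with a warning when scores are
    missing).
    """
    conditions = list(dict.fromkeys(samples["condition"]))
    ipa = meta[meta["region_class"] == "IPA"]
    rows = []
    for gene_id, grp in ipa.groupby("gene_id", sort=True):
        if gene_id is None:
            continue
        tpa = meta[(meta["gene_id"] == gene_id) & (meta["region_class"] == "TPA")]
        if tpa.empty:
            continue
        total_cols = [
            c for c in samples.index[samples["fraction"] == "total"] if c in counts
        ]
        tpa_tot = counts.loc[tpa.index, total_cols].sum(axis=1)
        ref_id = tpa_tot.idxmax()
        for ipa_id, irow in grp.iterrows():
            rec = {"gene_id": gene_id, "ipa_id": ipa_id, "tpa_id": ref_id,
                   "host_intron": int(irow.get("host_intron", -1))}
            if annotation is not None:
                gene = annotation.get(gene_id)
                hi = int(irow.get("host_intron", -1))
                if 0 <= hi < len(gene.introns):
                    intr = gene.introns[hi]
                    rec["intron_size"] = intr.size
                    rec["ss5_score"] = intr.ss5_score
                    rec["ss3_score"] = intr.ss3_score
            for cond in conditions:
                su = _pooled(rpm, samples, cond, "4sU")
                ft = _pooled(rpm, samples, cond, "FT")
                tot = _pooled(rpm, samples, cond, "total")
                if tpa_ref == "sum":
                    t_su = float(su[tpa.index].sum())
                    t_ft = float(ft[tpa.index].sum())
                    t_tot = float(tot[tpa.index].sum())
                else:
                    t_su, t_ft, t_tot = (
                        float(su[ref_id]),
                        float(ft[ref_id]),
                        float(tot[ref_id]),
                    )
                ss_ipa = stability_score(float(ft[ipa_id]), float(su[ipa_id]), pseudocount)
                ss_tpa = stability_score(t_ft, t_su, pseudocount)
                rec[f"SS_ipa_{cond}"] = ss_ipa
                rec[f"dSS_{cond}"] = ss_ipa - ss_tpa
                rec[f"rel_abund_{cond}"] = relative_expression(
                    float(tot[ipa_id]), t_tot, pseudocount
                )
            rows.append(rec)
    if not rows:
        return pd.DataFrame(), {}
    events = pd.DataFrame(rows).set_index("ipa_id")
    bins: dict[str, dict[str, BinAnalysis]] = {}
    for var in ("intron_size", "ss5_score", "ss3_score"):
        if var not in events.columns or events[var].isna().all():
            continue
        bins[var] = {}
        for cond in conditions:
            resp = events[f"SS_ipa_{cond}"]
            try:
                bins[var][cond] = quintile_bins(
                    events[var], resp, variable=var
                )
            except ValueError:
                continue
    return events, bins
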