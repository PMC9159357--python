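"""Desk-scale validation studies run on synthetic data.

Each function performs one self-contained study — simulate with known
ground truth, run the pipeline stage(s) under test, measure recovery —
and returns plain numbers.  They back both the acceptance test-suite
and the results-reproduction script, so every reported number is
recomputed from scratch on demand.
"""

from __future__ import annotations

import itertools
import math
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd
import pysam
from scipy import stats

from . import apa, discovery, quantify, sim
from .stability import stability_score, stability_table
from .features import regression_rank
from .structure import NussinovEngine, gini, n_windows, window_sequence


# ---------------------------------------------------------------------------
# stability-score kinetics


def kinetic_closed_form_error(n_k: int = 10, n_t: int = 10) -> float:
    """Max |SS(expected fractions) - log2(e^{-kt}/(1-e^{-kt}))| over a
    (k, t) grid — the labeling model's closed form."""
    ks = np.logspace(math.log10(0.05), math.log10(5.0), n_k)
    ts = np.linspace(0.25, 4.0, n_t)
    worst = 0.0
    for k in ks:
        for t in ts:
            _, labeled, unlabeled = sim.expected_fractions(1.0, k, t)
            ss = stability_score(unlabeled, labeled, pseudocount=0.0)
            ref = sim.implied_stability_score(k, t)
            worst = max(worst, abs(float(ss) - float(ref)))
    return worst


def ss_recovery_study(
    seed: int, n_genes: int = 500, depth: int = 200_000
) -> dict[str, float]:
    """Spearman correlation between measured SS and true log half-life.

    One cell line, two replicates, multinomial sampling at the given
    depth; SS computed through the full quantify + stability route on
    expression-filtered PASs.
    """
    cfg = sim.SimConfig(
        n_genes=n_genes, depth=depth, conditions=("lineA",), seed=seed
    )
    exp = sim.simulate_experiment(cfg)
    counts = quantify.filter_expressed(exp["counts"], min_reads=5)
    _, norm, _rpm = quantify.median_ratio_normalize(counts, exp["samples"])
    ss = stability_table(norm, exp["samples"], pseudocount=1.0)
    truth = exp["truth"].loc[ss.index]
    rho = stats.spearmanr(
        ss["SS_lineA"], np.log(truth["half_life"])
    ).statistic
    return {"spearman_ss_halflife": float(rho), "n": int(len(ss))}


# ---------------------------------------------------------------------------
# PAS discovery


def _simulate_sam(cfg: sim.SimConfig, tmpdir: Path, **align_kw) -> dict:
    exp = sim.simulate_experiment(cfg)
    rng = np.random.default_rng(cfg.seed + 17)
    paths = {}
    for sample_id in exp["counts"].columns:
        recs = sim.simulate_alignments(
            exp["counts"][sample_id],
            exp["truth"],
            exp["reference"],
            rng,
            read_length=cfg.read_length,
            clip_len=cfg.clip_len,
            **align_kw,
        )
        p = tmpdir / f"{sample_id}.sam"
        sim.write_sam(recs, exp["reference"], p)
        paths[sample_id] = str(p)
    exp["sam_paths"] = paths
    return exp


def pas_roundtrip_study(seed: int, n_genes: int = 60, depth: int = 20_000) -> dict:
    """Noise-free SAM round trip plus decoy precision.

    Without noise, called clusters must equal the simulated sites and
    counts exactly.  With 30% decoy (internal-priming-like) reads, no
    decoy may pass the >=2 non-genomic-T rule (precision 1.0 expected).
    """
    cfg = sim.SimConfig(
        n_genes=n_genes, depth=depth, conditions=("lineA",), replicates=1,
        seed=seed,
    )
    with tempfile.TemporaryDirectory() as td:
        exp = _simulate_sam(cfg, Path(td))
        sites = discovery.sites_from_sam(exp["sam_paths"], exp["reference"])
        clusters = discovery.assign_clusters(
            discovery.cluster_sites(sites), exp["annotation"]
        )
        meta, counts = discovery.clusters_to_frame(clusters)
        truth = exp["truth"]
        key_truth = {
            (r["chrom"], r["strand"], int(r["pas_pos"])): iso
            for iso, r in truth.iterrows()
        }
        matched = 0
        counts_exact = True
        for cid, row in meta.iterrows():
            key = (row["chrom"], row["strand"], int(row["summit"]))
            iso = key_truth.get(key)
            if iso is None:
                counts_exact = False
                continue
            matched += 1
            sim_counts = exp["counts"].loc[iso]
            got = counts.loc[cid].reindex(sim_counts.index).fillna(0)
            if not (got.to_numpy() == sim_counts.to_numpy()).all():
                counts_exact = False
        expressed = (exp["counts"].sum(axis=1) > 0).sum()
        site_recall = matched / int(expressed)
        # regions must match the simulated isoform class
        region_ok = all(
            meta.loc[cid, "region_class"]
            == truth.loc[
                key_truth[(meta.loc[cid, "chrom"], meta.loc[cid, "strand"],
                           int(meta.loc[cid, "summit"]))], "region_class"]
            for cid in meta.index
            if (meta.loc[cid, "chrom"], meta.loc[cid, "strand"],
                int(meta.loc[cid, "summit"])) in key_truth
        )

        # decoy run
        exp2 = _simulate_sam(
            sim.SimConfig(
                n_genes=n_genes, depth=depth, conditions=("lineA",),
                replicates=1, seed=seed + 1,
            ),
            Path(td),
            decoy_fraction=0.3,
        )
        n_called_real = n_called_decoy = 0
        for path in exp2["sam_paths"].values():
            with pysam.AlignmentFile(path, "r", check_sq=False) as fh:
                for rec in fh:
                    read = discovery.AlignedRead.from_pysam(rec)
                    if discovery.classify_read(read, exp2["reference"]) is None:
                        continue
                    if read.read_id.startswith("decoy"):
                        n_called_decoy += 1
                    else:
                        n_called_real += 1
        precision = (
            n_called_real / (n_called_real + n_called_decoy)
            if (n_called_real + n_called_decoy)
            else float("nan")
        )
    return {
        "site_recall": float(site_recall),
        "counts_exact": float(counts_exact),
        "regions_exact": float(region_ok),
        "decoy_precision": float(precision),
        "n_sites": int(len(meta)),
    }


def _oracle_cluster(
    positions: list[int], totals: list[int], window: int
) -> dict[int, int]:
    """Independent re-statement of the greedy clustering rule, written as
    literal repeated scans (oracle code path for cross-checking)."""
    remaining = set(range(len(positions)))
    result: dict[int, int] = {}
    while remaining:
        best = None
        for i in sorted(remaining):
            if (
                best is None
                or totals[i] > totals[best]
                or (totals[i] == totals[best] and positions[i] < positions[best])
            ):
                best = i
        absorbed = [
            i for i in remaining if abs(positions[i] - positions[best]) <= window
        ]
        result[positions[best]] = sum(totals[i] for i in absorbed)
        remaining -= set(absorbed)
    return result


def clustering_oracle_study(
    seed: int, n_instances: int = 1000, max_sites: int = 12, window: int = 24
) -> dict:
    """Greedy clustering vs the independent oracle on random instances;
    also checks count conservation and summit separation."""
    rng = np.random.default_rng(seed)
    mismatches = 0
    conservation_failures = 0
    separation_failures = 0
    for _ in range(n_instances):
        n = int(rng.integers(1, max_sites + 1))
        pos = sorted(rng.choice(200, size=n, replace=False).tolist())
        tot = rng.integers(1, 21, size=n).tolist()
        sites = [
            discovery.CleavageSite("chr1", "+", p, {"s": int(t)})
            for p, t in zip(pos, tot)
        ]
        got = {
            c.summit: c.total for c in discovery.cluster_sites(sites, window)
        }
        want = _oracle_cluster(pos, tot, window)
        if got != want:
            mismatches += 1
        if sum(got.values()) != sum(tot):
            conservation_failures += 1
        summits = sorted(got)
        if any(b - a <= window for a, b in zip(summits, summits[1:])):
            separation_failures += 1
    return {
        "instances": n_instances,
        "mismatches": mismatches,
        "conservation_failures": conservation_failures,
        "separation_failures": separation_failures,
    }


# ---------------------------------------------------------------------------
# differential stability


def anova_power_study(
    seed: int,
    n_genes: int = 200,
    depth: int = 200_000,
    perturbed_fraction: float = 0.10,
    k_scale: float = 2.0,
    alpha: float = 0.05,
) -> dict:
    """Power/FPR of the cross-condition ANOVA screen.

    One condition's decay rates are doubled for a random 10% of genes.
    A gene is represented by its most expressed PAS isoform (the same
    convention used for gene-level stability comparisons); power is the
    fraction of perturbed genes detected at p < alpha, the false-
    positive rate the same fraction among unperturbed genes.
    """
    cfg = sim.SimConfig(n_genes=n_genes, depth=depth, seed=seed)
    rng = np.random.default_rng(seed)
    ann, _ref = sim.simulate_annotation(cfg, rng)
    truth = sim.simulate_truth(ann, cfg, rng)
    gene_ids = sorted({g.gene_id for g in ann})
    n_pert = int(round(len(gene_ids) * perturbed_fraction))
    perturbed = set(
        rng.choice(np.array(gene_ids), size=n_pert, replace=False).tolist()
    )
    mask = truth["gene_id"].isin(perturbed)
    truth.loc[mask, f"k_{cfg.conditions[-1]}"] *= k_scale
    samples = sim.sample_sheet(cfg)
    expected = sim.expected_matrix(truth, samples, cfg.labeling_time)
    counts = sim.simulate_counts(expected, cfg.depth, rng)
    counts = quantify.filter_expressed(counts, min_reads=5)
    _, norm, _rpm = quantify.median_ratio_normalize(counts, samples)
    ss = stability_table(norm, samples, pseudocount=1.0)
    top = (
        counts.sum(axis=1)
        .groupby(truth.loc[counts.index, "gene_id"])
        .idxmax()
    )
    gene_p = ss.loc[top.to_numpy(), "anova_p"]
    gene_p.index = top.index
    hit = gene_p < alpha
    is_pert = pd.Series(gene_p.index.isin(perturbed), index=gene_p.index)
    power = float(hit[is_pert].mean())
    fpr = float(hit[~is_pert].mean())
    return {
        "anova_power": power,
        "anova_fpr": fpr,
        "n_perturbed": int(is_pert.sum()),
        "n_null": int((~is_pert).sum()),
    }


# ---------------------------------------------------------------------------
# APA isoform directionality


def isoform_direction_study(
    seed: int, n_genes: int = 300, depth: int = 200_000
) -> dict:
    """Directional behaviour of 3'UTR isoform analytics.

    All genes carry two TPA PASs.  Half the genes get k(dPAS) =
    4 k(pPAS) in every condition (destabilized long isoform); in
    condition B every dPAS is additionally stabilized two-fold.
    Expectations: more blue (pPAS-more-stable) than red calls;
    RE higher in 4sU than FT for perturbed genes; median RED(B - A) > 0.
    """
    cfg = sim.SimConfig(
        n_genes=n_genes,
        depth=depth,
        pas_per_gene_probs={2: 1.0},
        ipa_probability=0.0,
        dpas_k_ratio=1.0,
        dpas_k_sigma=0.0,
        conditions=("lineA", "lineB"),
        seed=seed,
    )
    rng = np.random.default_rng(seed)
    ann, _ref = sim.simulate_annotation(cfg, rng)
    truth = sim.simulate_truth(ann, cfg, rng)
    gene_ids = sorted({g.gene_id for g in ann})
    perturbed = set(gene_ids[: len(gene_ids) // 2])
    is_d = truth["pas_rank"] == 2
    mask = is_d & truth["gene_id"].isin(perturbed)
    for cond in cfg.conditions:
        truth.loc[mask, f"k_{cond}"] *= 4.0
    truth.loc[is_d, "k_lineB"] /= 2.0  # dPAS stabilized in condition B
    samples = sim.sample_sheet(cfg)
    expected = sim.expected_matrix(truth, samples, cfg.labeling_time)
    counts = sim.simulate_counts(expected, cfg.depth, rng)
    counts = quantify.filter_expressed(counts, min_reads=5)
    _, norm, _rpm = quantify.median_ratio_normalize(counts, samples)

    meta = pd.DataFrame(
        {
            "chrom": truth.loc[counts.index, "chrom"],
            "strand": truth.loc[counts.index, "strand"],
            "summit": truth.loc[counts.index, "pas_pos"].astype(int),
            "gene_id": truth.loc[counts.index, "gene_id"],
            "region_class": truth.loc[counts.index, "region_class"],
        }
    )
    pairs = apa.select_pairs(meta, counts, samples)
    table = apa.pair_stability_table(pairs, counts, norm, samples)
    n_blue, n_red, ratio = apa.blue_red_ratio(table, "lineA")
    pert_rows = table.index.isin(perturbed)
    re_diff = (
        table.loc[pert_rows, "RE_lineA_4sU"] - table.loc[pert_rows, "RE_lineA_FT"]
    )
    red_ba = apa.red(
        table["RE_lineB_total"].to_numpy(), table["RE_lineA_total"].to_numpy()
    )
    return {
        "n_blue": n_blue,
        "n_red": n_red,
        "blue_red_ratio": float(ratio),
        "median_re_4su_minus_ft_perturbed": float(np.median(re_diff)),
        "frac_re_4su_gt_ft_perturbed": float((re_diff > 0).mean()),
        "median_red_b_minus_a": float(np.nanmedian(red_ba)),
        "n_pairs": int(len(table)),
    }


def ipa_direction_study(
    seed: int, n_genes: int = 300, depth: int = 200_000
) -> dict:
    """Directional behaviour of intronic-PAS analytics.

    Every gene carries one intronic PAS with k(IPA) = 3 k(gene): median
    dSS(IPA - TPA) must be negative.  A second simulation couples
    k(IPA) to host-intron size: the bin-1 vs bin-5 rank-sum test on
    SS(IPA) must reject with the larger-intron bin less stable.
    """
    cfg = sim.SimConfig(
        n_genes=n_genes,
        depth=depth,
        ipa_probability=1.0,
        ipa_k_ratio=3.0,
        ipa_k_sigma=0.0,
        conditions=("lineA",),
        seed=seed,
    )
    rng = np.random.default_rng(seed)
    ann, _ref = sim.simulate_annotation(cfg, rng)
    truth = sim.simulate_truth(ann, cfg, rng)
    samples = sim.sample_sheet(cfg)
    expected = sim.expected_matrix(truth, samples, cfg.labeling_time)
    counts = sim.simulate_counts(expected, cfg.depth, rng)
    counts = quantify.filter_expressed(counts, min_reads=5)
    _, norm, _rpm = quantify.median_ratio_normalize(counts, samples)
    meta = pd.DataFrame(
        {
            "chrom": truth.loc[counts.index, "chrom"],
            "strand": truth.loc[counts.index, "strand"],
            "summit": truth.loc[counts.index, "pas_pos"].astype(int),
            "gene_id": truth.loc[counts.index, "gene_id"],
            "region_class": truth.loc[counts.index, "region_class"],
            "host_intron": truth.loc[counts.index, "host_intron"],
        }
    )
    events, _bins = apa.ipa_analysis(meta, counts, norm, samples, annotation=ann)
    median_dss = float(np.nanmedian(events["dSS_lineA"]))

    # second simulation: k(IPA) coupled to host-intron size
    truth2 = sim.simulate_truth(ann, cfg, np.random.default_rng(seed + 1))
    ipa_mask = truth2["region_class"] == "IPA"
    size = truth2.loc[ipa_mask, "intron_size"]
    coupling = (size / float(np.exp(np.log(size).mean()))) ** 0.8
    truth2.loc[ipa_mask, "k_lineA"] = truth2.loc[ipa_mask, "k_lineA"] * coupling
    expected2 = sim.expected_matrix(truth2, samples, cfg.labeling_time)
    counts2 = sim.simulate_counts(expected2, cfg.depth, rng)
    counts2 = quantify.filter_expressed(counts2, min_reads=5)
    _, norm2, _rpm2 = quantify.median_ratio_normalize(counts2, samples)
    meta2 = pd.DataFrame(
        {
            "chrom": truth2.loc[counts2.index, "chrom"],
            "strand": truth2.loc[counts2.index, "strand"],
            "summit": truth2.loc[counts2.index, "pas_pos"].astype(int),
            "gene_id": truth2.loc[counts2.index, "gene_id"],
            "region_class": truth2.loc[counts2.index, "region_class"],
            "host_intron": truth2.loc[counts2.index, "host_intron"],
        }
    )
    events2, bins2 = apa.ipa_analysis(meta2, counts2, norm2, samples, annotation=ann)
    ba = bins2["intron_size"]["lineA"]
    bin1 = events2.loc[ba.assignment[ba.assignment == 1].index, "SS_ipa_lineA"]
    bin5 = events2.loc[
        ba.assignment[ba.assignment == ba.n_bins].index, "SS_ipa_lineA"
    ]
    return {
        "median_dss_ipa_minus_tpa": median_dss,
        "n_ipa_events": int(len(events)),
        "intron_size_bin_p": float(ba.comparison.pvalue),
        "bin1_minus_bin5_median_ss": float(
            np.median(bin1) - np.median(bin5)
        ),
    }


# ---------------------------------------------------------------------------
# exact-test oracles


def fisher_oracle_two_sided(table: list[list[int]]) -> float:
    """Two-sided Fisher p by exhaustive hypergeometric enumeration."""
    (a, b), (c, d) = table
    row1, col1, n = a + b, a + c, a + b + c + d
    lo, hi = max(0, row1 + col1 - n), min(row1, col1)
    probs = {x: stats.hypergeom.pmf(x, n, row1, col1) for x in range(lo, hi + 1)}
    p_obs = probs[a]
    return float(min(1.0, sum(p for p in probs.values() if p <= p_obs * (1 + 1e-9))))


def ranksum_oracle_two_sided(a: list[float], b: list[float]) -> float:
    """Two-sided rank-sum p by full permutation enumeration (no ties)."""
    pooled = list(a) + list(b)
    n1 = len(a)
    n1n2 = n1 * len(b)

    def u_stat(group_a: tuple[float, ...]) -> int:
        rest = list(pooled)
        for x in group_a:
            rest.remove(x)
        return sum(1 for x in group_a for y in rest if x > y)

    u_obs = u_stat(tuple(a))
    lo_obs = min(u_obs, n1n2 - u_obs)
    hits = total = 0
    for combo in itertools.combinations(range(len(pooled)), n1):
        u = u_stat(tuple(pooled[i] for i in combo))
        if min(u, n1n2 - u) <= lo_obs:
            hits += 1
        total += 1
    return hits / total


def exact_test_oracle_study(seed: int, n_fisher: int = 500, n_ranksum: int = 50) -> dict:
    """Library exact tests vs brute-force enumeration oracles."""
    rng = np.random.default_rng(seed)
    worst_fisher = 0.0
    for _ in range(n_fisher):
        tbl = [[int(rng.integers(0, 21)) for _ in range(2)] for _ in range(2)]
        if sum(tbl[0]) + sum(tbl[1]) == 0:
            continue
        _, p = stats.fisher_exact(tbl, alternative="two-sided")
        worst_fisher = max(worst_fisher, abs(p - fisher_oracle_two_sided(tbl)))
    worst_rs = 0.0
    for _ in range(n_ranksum):
        n1 = int(rng.integers(2, 8))
        n2 = int(rng.integers(2, 8))
        vals = rng.choice(1000, size=n1 + n2, replace=False).astype(float)
        a, b = vals[:n1].tolist(), vals[n1:].tolist()
        p = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact").pvalue
        worst_rs = max(worst_rs, abs(float(p) - ranksum_oracle_two_sided(a, b)))
    return {"fisher_max_abs_err": worst_fisher, "ranksum_max_abs_err": worst_rs}


# ---------------------------------------------------------------------------
# feature regression


def regression_recovery_study(
    seed: int, n_replicates: int = 100, n: int = 2000, noise_sd: float = 0.5
) -> dict:
    """Planted-coefficient recovery: response = 0.8 zGC - 0.4 zU + noise.

    Per replicate, per-gene GC and U contents (plus two nuisance
    features) are drawn, the response built from their z-scores, and the
    R^2 ranking must put GC first with a positive sign and U with a
    negative sign.
    """
    rng = np.random.default_rng(seed)
    successes = 0
    for _ in range(n_replicates):
        gc = rng.uniform(0.30, 0.70, size=n)
        u_share = rng.uniform(0.30, 0.70, size=n)
        u = u_share * (1.0 - gc)
        size = np.exp(rng.normal(6.5, 0.8, size=n))
        jd = rng.uniform(0.0, 5.0, size=n)
        z = lambda x: (x - x.mean()) / x.std()
        y = 0.8 * z(gc) - 0.4 * z(u) + rng.normal(0.0, noise_sd, size=n)
        feats = pd.DataFrame(
            {"utr3_GC": gc, "utr3_U": u, "utr3_size": size, "junction_density": jd}
        )
        report = regression_rank(feats, pd.Series(y))
        ok = (
            report.index[0] == "utr3_GC"
            and report.loc["utr3_GC", "sign"] > 0
            and report.loc["utr3_U", "sign"] < 0
            and report.index.get_loc("utr3_GC") < report.index.get_loc("utr3_U")
        )
        successes += int(ok)
    return {"n_replicates": n_replicates, "n_recovered": successes}


# ---------------------------------------------------------------------------
# structure scoring


def structure_checks(seed: int, n_shuffles: int = 100) -> dict:
    """Window-tiling formula, Gini hand values, hairpin vs shuffle MFE."""
    tiling_failures = sum(
        1
        for L in range(1, 1001)
        if len(window_sequence("N" * L)) != n_windows(L)
    )
    g_equal = gini([1, 1, 1, 1])
    g_single = gini([0, 0, 0, 1])
    engine = NussinovEngine()
    hairpin = "GGGGGAAAACCCCC"
    mfe = engine.fold(hairpin)
    rng = np.random.default_rng(seed)
    shuffled = []
    letters = np.array(list(hairpin))
    for _ in range(n_shuffles):
        shuffled.append(engine.fold("".join(rng.permutation(letters))))
    return {
        "tiling_failures": tiling_failures,
        "gini_equal": float(g_equal),
        "gini_single": float(g_single),
        "hairpin_mfe": float(mfe),
        "shuffle_mean_mfe": float(np.mean(shuffled)),
    }
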