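"""End-to-end orchestration: simulate -> call PASs -> quantify ->
stability -> APA/IPA -> features -> structure, with TSV outputs and a
run summary.

Every stage writes plain-text tables into the run directory; the run is
deterministic given the seed, and every configurable threshold is logged
with its value.  ``resume=True`` skips stages whose outputs already
exist.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import apa, discovery, quantify, sim
from .annotation import read_gtf, write_gtf
from .features import compute_features, regression_rank
from .stability import stability_table
from .structure import NussinovEngine, get_engine, median_mfe, n_windows

logger = logging.getLogger(__name__)

_TSV_KW = dict(sep="\t")  # default float formatting round-trips exactly


@dataclass
class RunConfig:
    """Thresholds and inputs of one pipeline run.

    Defaults mirror the analysis conventions: mapping quality >= 10,
    >= 2 non-genomic 5' Ts, 24-nt cleavage-site clustering, >= 5 reads
    in at least one sample, p < 0.05 with relative-abundance difference
    > 5% for usage calls, FDR < 0.05 for stability calls.
    """

    outdir: str = "run"
    sim: sim.SimConfig = field(default_factory=lambda: sim.SimConfig(
        n_genes=60, depth=20_000
    ))
    min_mapq: int = 10
    min_clip_t: int = 2
    cluster_window: int = 24
    min_reads: int = 5
    strict_gt5: bool = False
    pseudocount: float = 1.0
    alpha: float = 0.05
    fdr: float = 0.05
    rel_abund: float = 0.05
    contrast: Optional[tuple[str, str]] = None
    structure_engine: str = "builtin"
    seed: int = 0
    resume: bool = False

    def thresholds(self) -> dict:
        return {
            "min_mapq": self.min_mapq,
            "min_clip_t": self.min_clip_t,
            "cluster_window": self.cluster_window,
            "min_reads": self.min_reads,
            "strict_gt5": self.strict_gt5,
            "pseudocount": self.pseudocount,
            "alpha": self.alpha,
            "fdr": self.fdr,
            "rel_abund": self.rel_abund,
            "seed": self.seed,
        }


def _read_tsv(path: Path, index_col=0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage; returns the summary dict (also written as JSON
    and markdown).  Partial outputs are retained on stage failure."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    for key, value in config.thresholds().items():
        logger.info("threshold %s = %s", key, value)
    state: dict = {"config": config}
    stages = [
        ("simulate", _stage_simulate),
        ("callpas", _stage_callpas),
        ("quantify", _stage_quantify),
        ("stability", _stage_stability),
        ("apa", _stage_apa),
        ("ipa", _stage_ipa),
        ("features", _stage_features),
        ("structure", _stage_structure),
        ("summary", _stage_summary),
    ]
    for name, fn in stages:
        t0 = time.perf_counter()
        try:
            fn(config, out, state)
        except Exception as exc:
            raise PipelineError(name, exc) from exc
        logger.info("stage %s finished in %.2fs", name, time.perf_counter() - t0)
    return state["summary"]


def _stage_simulate(config: RunConfig, out: Path, state: dict) -> None:
    scfg = sim.SimConfig(**{**config.sim.to_dict(), "seed": config.seed})
    gtf, fa = out / "annotation.gtf", out / "reference.fa"
    truth_p, samples_p = out / "truth.tsv", out / "samples.tsv"
    sam_dir = out / "sam"
    if config.resume and gtf.exists() and truth_p.exists():
        ann = read_gtf(str(gtf))
        reference = _read_fasta(fa)
        truth = _read_tsv(truth_p)
        samples = _read_tsv(samples_p)
        state.update(annotation=ann, reference=reference, truth=truth, samples=samples)
        state["sam_paths"] = {
            s: str(sam_dir / f"{s}.sam") for s in samples.index
        }
        return
    rng = np.random.default_rng(scfg.seed)
    ann, reference = sim.simulate_annotation(scfg, rng)
    truth = sim.simulate_truth(ann, scfg, rng)
    samples = sim.sample_sheet(scfg)
    expected = sim.expected_matrix(truth, samples, scfg.labeling_time, scfg.contamination)
    counts = sim.simulate_counts(expected, scfg.depth, rng)
    write_gtf(ann, str(gtf))
    sim.write_fasta(reference, fa)
    truth.to_csv(truth_p, **_TSV_KW)
    samples.to_csv(samples_p, **_TSV_KW)
    expected.to_csv(out / "expected_abundance.tsv", **_TSV_KW)
    sam_dir.mkdir(exist_ok=True)
    sam_paths = {}
    for sample_id in counts.columns:
        recs = sim.simulate_alignments(
            counts[sample_id], truth, reference, rng,
            read_length=scfg.read_length, clip_len=scfg.clip_len,
            microheterogeneity=scfg.microheterogeneity,
            decoy_fraction=scfg.decoy_fraction,
            lowmapq_fraction=scfg.lowmapq_fraction,
        )
        p = sam_dir / f"{sample_id}.sam"
        sim.write_sam(recs, reference, p)
        sam_paths[sample_id] = str(p)
    state.update(
        annotation=ann, reference=reference, truth=truth, samples=samples,
        sam_paths=sam_paths,
    )


def _read_fasta(path: Path) -> dict[str, str]:
    seqs: dict[str, list[str]] = {}
    name = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                name = line[1:].split()[0]
                seqs[name] = []
            elif name is not None:
                seqs[name].append(line)
    return {k: "".join(v) for k, v in seqs.items()}


def _stage_callpas(config: RunConfig, out: Path, state: dict) -> None:
    meta_p, counts_p = out / "cluster_meta.tsv", out / "cluster_counts.tsv"
    if config.resume and meta_p.exists() and counts_p.exists():
        state["cluster_meta"] = _read_tsv(meta_p)
        state["cluster_counts"] = _read_tsv(counts_p)
        return
    sites = discovery.sites_from_sam(
        state["sam_paths"], state["reference"],
        min_mapq=config.min_mapq, min_clip_t=config.min_clip_t,
    )
    clusters = discovery.cluster_sites(sites, window=config.cluster_window)
    clusters = discovery.assign_clusters(clusters, state["annotation"])
    discovery.write_bed(clusters, str(out / "clusters.bed"))
    meta, counts = discovery.clusters_to_frame(clusters)
    meta.to_csv(meta_p, **_TSV_KW)
    counts.to_csv(counts_p, **_TSV_KW)
    state["cluster_meta"], state["cluster_counts"] = meta, counts
    logger.info("called %d PAS clusters from %d cleavage sites", len(meta), len(sites))


def _stage_quantify(config: RunConfig, out: Path, state: dict) -> None:
    rpm_p = out / "rpm.tsv"
    norm_p = out / "normalized_counts.tsv"
    if config.resume and rpm_p.exists() and norm_p.exists():
        state["counts"] = _read_tsv(out / "filtered_counts.tsv")
        state["norm"] = _read_tsv(norm_p)
        state["rpm"] = _read_tsv(rpm_p)
        state["size_factors"] = _read_tsv(out / "size_factors.tsv")["size_factor"]
        return
    counts = quantify.filter_expressed(
        state["cluster_counts"], config.min_reads, config.strict_gt5
    )
    logger.info(
        "expression filter (>=%d reads): %d of %d clusters kept",
        config.min_reads, len(counts), len(state["cluster_counts"]),
    )
    factors, norm, rpm = quantify.median_ratio_normalize(counts, state["samples"])
    counts.to_csv(out / "filtered_counts.tsv", **_TSV_KW)
    factors.rename("size_factor").to_csv(out / "size_factors.tsv", **_TSV_KW)
    norm.to_csv(norm_p, **_TSV_KW)
    rpm.to_csv(rpm_p, **_TSV_KW)
    state.update(counts=counts, norm=norm, rpm=rpm, size_factors=factors)


def _stage_stability(config: RunConfig, out: Path, state: dict) -> None:
    p = out / "stability.tsv"
    if config.resume and p.exists():
        state["stability"] = _read_tsv(p)
        return
    ss = stability_table(state["norm"], state["samples"], config.pseudocount)
    ss.to_csv(p, **_TSV_KW)
    state["stability"] = ss


def _meta_subset(state: dict) -> pd.DataFrame:
    meta = state["cluster_meta"]
    return meta.loc[meta.index.intersection(state["counts"].index)]


def _stage_apa(config: RunConfig, out: Path, state: dict) -> None:
    pairs_p = out / "apa_pairs.tsv"
    if config.resume and pairs_p.exists():
        state["apa_pairs"] = _read_tsv(pairs_p)
        usage_p = out / "apa_usage.tsv"
        state["apa_usage"] = _read_tsv(usage_p) if usage_p.exists() else None
        return
    meta = _meta_subset(state)
    samples = state["samples"]
    pairs = apa.select_pairs(meta, state["counts"], samples)
    if pairs.empty:
        state["apa_pairs"], state["apa_usage"] = pairs, None
        pairs.to_csv(pairs_p, **_TSV_KW)
        return
    table = apa.pair_stability_table(
        pairs, state["counts"], state["norm"], samples,
        pseudocount=config.pseudocount, alpha_fdr=config.fdr,
    )
    table.to_csv(pairs_p, **_TSV_KW)
    conditions = list(dict.fromkeys(samples["condition"]))
    contrast = config.contrast or (
        tuple(conditions[:2]) if len(conditions) >= 2 else None
    )
    usage = None
    if contrast:
        usage = apa.usage_shift_table(
            pairs, state["counts"], samples, contrast[0], contrast[1],
            alpha=config.alpha, min_rel_diff=config.rel_abund,
        )
        usage.to_csv(out / "apa_usage.tsv", **_TSV_KW)
    state["apa_pairs"], state["apa_usage"] = table, usage
    state["contrast"] = contrast


def _stage_ipa(config: RunConfig, out: Path, state: dict) -> None:
    p = out / "ipa_events.tsv"
    if config.resume and p.exists():
        state["ipa_events"] = _read_tsv(p)
        return
    meta = _meta_subset(state)
    events, bins = apa.ipa_analysis(
        meta, state["counts"], state["norm"], state["samples"],
        annotation=state["annotation"], pseudocount=config.pseudocount,
    )
    events.to_csv(p, **_TSV_KW)
    state["ipa_events"], state["ipa_bins"] = events, bins


def _stage_features(config: RunConfig, out: Path, state: dict) -> None:
    p = out / "features.tsv"
    if config.resume and p.exists():
        state["features"] = _read_tsv(p)
        return
    meta = _meta_subset(state)
    pairs = state["apa_pairs"]
    feats = compute_features(
        state["annotation"], state["reference"],
        pairs=pairs if not pairs.empty else None, clusters=meta,
    )
    feats.to_csv(p, **_TSV_KW)
    state["features"] = feats
    # response: per-gene dSS between the contrast conditions (top isoform)
    contrast = state.get("contrast")
    if not contrast:
        return
    ss = state["stability"]
    cond_a, cond_b = contrast
    gene_ss = {}
    counts = state["counts"]
    tpa = meta[meta["region_class"] == "TPA"]
    for gene_id, grp in tpa.groupby("gene_id"):
        top = counts.loc[grp.index].sum(axis=1).idxmax()
        if top in ss.index:
            gene_ss[gene_id] = ss.loc[top, f"SS_{cond_b}"] - ss.loc[top, f"SS_{cond_a}"]
    response = pd.Series(gene_ss, name=f"dSS_{cond_b}_vs_{cond_a}")
    cols = [
        "gene_GC", "gene_U", "utr3_GC", "utr3_U", "utr3_size", "gene_size",
        "junction_density", "pas_count_utr3",
    ]
    try:
        report = regression_rank(feats.loc[response.index, cols], response)
        report.to_csv(out / "regression.tsv", **_TSV_KW)
        state["regression"] = report
    except ValueError as exc:
        logger.warning("feature regression skipped: %s", exc)


def _stage_structure(config: RunConfig, out: Path, state: dict) -> None:
    p = out / "structure.tsv"
    if config.resume and p.exists():
        state["structure"] = _read_tsv(p)
        return
    engine = get_engine(config.structure_engine)
    rows = []
    for gene in state["annotation"]:
        span = gene.utr3_span()
        if span is None:
            continue
        seq = state["reference"][gene.chrom][span[0] : span[1]]
        rows.append(
            {
                "region_id": gene.gene_id,
                "length": len(seq),
                "n_windows": n_windows(len(seq)),
                "median_MFE": median_mfe(seq, engine),
            }
        )
    table = pd.DataFrame(rows).set_index("region_id")
    table.to_csv(p, **_TSV_KW)
    state["structure"] = table


def _stage_summary(config: RunConfig, out: Path, state: dict) -> None:
    samples = state["samples"]
    conditions = list(dict.fromkeys(samples["condition"]))
    meta = _meta_subset(state)
    pairs = state["apa_pairs"]
    summary: dict = {
        "thresholds": config.thresholds(),
        "n_pas_clusters": int(len(state["cluster_meta"])),
        "n_pas_expressed": int(len(state["counts"])),
        "n_genes_detected": int(meta["gene_id"].dropna().nunique()),
        "n_genes_with_apa_pair": int(len(pairs)),
        "n_ipa_events": int(len(state["ipa_events"])),
        "region_class_counts": {
            k: int(v) for k, v in meta["region_class"].value_counts().items()
        },
    }
    for cond in conditions:
        block: dict = {}
        if not pairs.empty:
            for frac in ("total", "4sU", "FT"):
                col = f"RE_{cond}_{frac}"
                if col in pairs:
                    block[f"median_RE_{frac}"] = round(
                        float(pairs[col].median()), 6
                    )
            n_blue, n_red, ratio = apa.blue_red_ratio(pairs, cond)
            block.update(
                n_blue=n_blue, n_red=n_red,
                blue_red_ratio=round(ratio, 6) if np.isfinite(ratio) else None,
            )
        ev = state["ipa_events"]
        if len(ev):
            block["median_dSS_ipa_minus_tpa"] = round(
                float(np.nanmedian(ev[f"dSS_{cond}"])), 6
            )
        ss = state["stability"]
        by_type: dict = {}
        gt = meta["gene_id"].map(
            {g.gene_id: g.gene_type for g in state["annotation"]}
        )
        for gene_type, idx in ss.index.to_series().groupby(gt.reindex(ss.index)):
            by_type[gene_type] = round(
                float(ss.loc[idx, f"SS_{cond}"].median()), 6
            )
        block["median_SS_by_gene_type"] = by_type
        summary[f"condition_{cond}"] = block
    state["summary"] = summary
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    with open(out / "summary.md", "w") as fh:
        fh.write("# Run summary\n\n")
        fh.write(f"- PAS clusters: {summary['n_pas_clusters']}\n")
        fh.write(f"- expressed PAS clusters: {summary['n_pas_expressed']}\n")
        fh.write(f"- genes detected: {summary['n_genes_detected']}\n")
        fh.write(f"- genes with 3'UTR APA pair: {summary['n_genes_with_apa_pair']}\n")
        fh.write(f"- IPA events: {summary['n_ipa_events']}\n\n")
        fh.write("```json\n")
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n```\n")
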