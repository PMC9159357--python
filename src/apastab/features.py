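"""Sequence/architecture features, R^2 ranking, hexamer enrichment.

Features are computed on the sense strand of each transcript: GC and U
content of the whole mature transcript, the 3'-most exon, the 3'UTR and
the aUTR (pPAS -> dPAS interval); region sizes; exon-junction density
per kilobase of mature transcript; number of PASs in the 3'UTR.  Their
association with a response (a stability score or its difference) is
ranked by individual R^2 (squared Pearson correlation) and cumulative
R^2 of nested least-squares fits along that ranking.
"""

from __future__ import annotations

from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._seq import gc_fraction, revcomp, u_fraction
from .annotation import GenomeAnnotation

ALPHABET = "ACGT"
HEXAMERS = [
    a + b + c + d + e + f
    for a in ALPHABET
    for b in ALPHABET
    for c in ALPHABET
    for d in ALPHABET
    for e in ALPHABET
    for f in ALPHABET
]


def _sense(seq: str, strand: str) -> str:
    return seq if strand == "+" else revcomp(seq)


def region_sequence(
    reference: Mapping[str, str], chrom: str, lo: int, hi: int, strand: str
) -> str:
    """Sense-strand sequence of a genomic span (0-based half-open)."""
    seq = reference[chrom]
    if lo < 0 or hi > len(seq) or lo > hi:
        raise ValueError(f"region {chrom}:{lo}-{hi} outside reference")
    return _sense(seq[lo:hi], strand)


def compute_features(
    ann: GenomeAnnotation,
    reference: Mapping[str, str],
    pairs: Optional[pd.DataFrame] = None,
    clusters: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Per-gene feature vectors.

    ``pairs`` (from :func:`apastab.apa.select_pairs`) supplies the
    pPAS/dPAS summits delimiting the aUTR; genes without a pair get NaN
    aUTR features.  ``clusters`` (PAS metadata with ``gene_id`` and
    ``region_class``) supplies the observed 3'UTR PAS count; without it
    the annotated PAS positions are counted.
    """
    rows = []
    for g in ann:
        mature = "".join(
            _sense(reference[g.chrom][s:e], g.strand)
            for s, e in (g.exons if g.strand == "+" else reversed(g.exons))
        )
        le = g.last_exon
        le_seq = region_sequence(reference, g.chrom, le[0], le[1], g.strand)
        utr = g.utr3_span()
        utr_seq = (
            region_sequence(reference, g.chrom, utr[0], utr[1], g.strand)
            if utr
            else ""
        )
        rec = {
            "gene_id": g.gene_id,
            "gene_GC": gc_fraction(mature),
            "gene_U": u_fraction(mature),
            "lastexon_GC": gc_fraction(le_seq),
            "utr3_GC": gc_fraction(utr_seq) if utr_seq else np.nan,
            "utr3_U": u_fraction(utr_seq) if utr_seq else np.nan,
            "gene_size": g.mature_length,
            "utr3_size": len(utr_seq) if utr_seq else np.nan,
            "junction_density": g.n_junctions / (g.mature_length / 1000.0),
        }
        if clusters is not None:
            rec["pas_count_utr3"] = int(
                (
                    (clusters["gene_id"] == g.gene_id)
                    & (clusters["region_class"] == "TPA")
                ).sum()
            )
        else:
            rec["pas_count_utr3"] = len(g.pas_positions)
        if pairs is not None and g.gene_id in pairs.index:
            pr = pairs.loc[g.gene_id]
            lo = int(min(pr["p_summit"], pr["d_summit"]))
            hi = int(max(pr["p_summit"], pr["d_summit"])) + 1
            autr_seq = region_sequence(reference, g.chrom, lo, hi, g.strand)
            rec["aUTR_GC"] = gc_fraction(autr_seq)
            rec["aUTR_U"] = u_fraction(autr_seq)
            rec["aUTR_size"] = len(autr_seq)
        else:
            rec["aUTR_GC"] = np.nan
            rec["aUTR_U"] = np.nan
            rec["aUTR_size"] = np.nan
        rows.append(rec)
    return pd.DataFrame(rows).set_index("gene_id")


def regression_rank(features: pd.DataFrame, response: pd.Series) -> pd.DataFrame:
    """Rank features by individual R^2 and report cumulative R^2.

    Rows with any missing value are dropped.  Individual R^2 is the
    squared Pearson correlation of a single feature with the response
    (equal to the one-variable least-squares R^2); the sign column is
    the sign of that correlation.  Features are sorted by decreasing
    individual R^2 and the cumulative R^2 at rank j is the R^2 of an
    ordinary least-squares fit on the top-j features (z-scored;
    constant features get individual R^2 = 0 and are excluded from the
    cumulative fit).  Cumulative R^2 is non-decreasing along the order.
    """
    df = features.copy()
    df["__y"] = response
    df = df.dropna()
    if len(df) <= len(features.columns) + 1:
        raise ValueError("need more observations than features")
    y = df.pop("__y").to_numpy(dtype=float)
    X = df.to_numpy(dtype=float)
    names = list(df.columns)
    sd = X.std(axis=0)
    const = sd == 0
    r2 = np.zeros(len(names))
    sign = np.zeros(len(names))
    yc = y - y.mean()
    for j in range(len(names)):
        if const[j]:
            continue
        r = np.corrcoef(X[:, j], y)[0, 1]
        r2[j] = r * r
        sign[j] = np.sign(r)
    order = np.argsort(-r2, kind="stable")
    Z = (X - X.mean(axis=0)) / np.where(const, 1.0, sd)
    cum = np.full(len(names), np.nan)
    active: list[int] = []
    sst = float((yc**2).sum())
    for rank, j in enumerate(order):
        if not const[j]:
            active.append(j)
        if active:
            A = np.column_stack([np.ones(len(y)), Z[:, active]])
            beta, *_ = np.linalg.lstsq(A, y, rcond=None)
            resid = y - A @ beta
            cum[rank] = 1.0 - float((resid**2).sum()) / sst
        else:
            cum[rank] = 0.0
    out = pd.DataFrame(
        {
            "feature": [names[j] for j in order],
            "r2_individual": r2[order],
            "sign": sign[order],
            "r2_cumulative": np.maximum.accumulate(np.nan_to_num(cum)),
        }
    ).set_index("feature")
    return out


def count_hexamers(sequences: Sequence[str], per_sequence: bool = False) -> pd.Series:
    """Overlapping hexamer occurrence counts pooled over sequences.

    ``per_sequence`` counts presence/absence per sequence instead of
    occurrences.
    """
    counts: dict[str, int] = {}
    for seq in sequences:
        seq = seq.upper().replace("U", "T")
        seen = set()
        for i in range(len(seq) - 5):
            h = seq[i : i + 6]
            if any(b not in ALPHABET for b in h):
                continue
            if per_sequence:
                seen.add(h)
            else:
                counts[h] = counts.get(h, 0) + 1
        for h in seen:
            counts[h] = counts.get(h, 0) + 1
    return pd.Series(counts, dtype=int).reindex(HEXAMERS, fill_value=0)


def hexamer_enrichment(
    fg_sequences: Sequence[str],
    bg_sequences: Sequence[str],
    per_sequence: bool = False,
    top_k: int = 10,
    q_threshold: float = 0.05,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Hexamer enrichment of foreground vs background sequence sets.

    Per hexamer, a 2x2 Fisher exact test on [this hexamer, all others] x
    [fg, bg] occurrence counts, with BH q-values.  The top ``top_k``
    enriched hexamers (odds ratio > 1, q < ``q_threshold``) are stacked
    ungapped into a 4 x 6 position-frequency matrix (rows A, C, G, U).
    Returns (table over all 4096 hexamers, position-frequency matrix).
    """
    if not fg_sequences or not bg_sequences:
        raise ValueError("empty sequence set")
    fg = count_hexamers(fg_sequences, per_sequence)
    bg = count_hexamers(bg_sequences, per_sequence)
    fg_tot, bg_tot = int(fg.sum()), int(bg.sum())
    pvals = np.ones(len(HEXAMERS))
    odds = np.ones(len(HEXAMERS))
    fg_np, bg_np = fg.to_numpy(), bg.to_numpy()
    for i in range(len(HEXAMERS)):
        a, b = int(fg_np[i]), int(bg_np[i])
        if a == 0 and b == 0:
            continue
        o, p = stats.fisher_exact(
            [[a, fg_tot - a], [b, bg_tot - b]], alternative="two-sided"
        )
        pvals[i], odds[i] = p, o
    q = multipletests(pvals, method="fdr_bh")[1]
    table = pd.DataFrame(
        {
            "fg_count": fg_np,
            "bg_count": bg_np,
            "odds_ratio": odds,
            "p": pvals,
            "q": q,
        },
        index=pd.Index(HEXAMERS, name="hexamer"),
    )
    enriched = table[(table["odds_ratio"] > 1) & (table["q"] < q_threshold)]
    enriched = enriched.sort_values(["q", "p", "odds_ratio"], ascending=[True, True, False])
    top = list(enriched.index[:top_k])
    pfm = np.zeros((4, 6))
    if top:
        for h in top:
            for pos, base in enumerate(h):
                pfm["ACGT".index(base), pos] += 1
        pfm /= len(top)
    return table, pfm


def write_meme_motif(pfm: np.ndarray, path: str, name: str = "motif1") -> None:
    """Write a 4x6 position-frequency matrix in MEME minimal format."""
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGU\n\n")
        fh.write(f"MOTIF {name}\n")
        fh.write("letter-probability matrix: alength= 4 w= 6\n")
        for col in pfm.T:
            fh.write(" ".join(f"{x:.6f}" for x in col) + "\n")
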