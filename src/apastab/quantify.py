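"""Count-matrix filtering and median-ratio (size-factor) normalization."""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd


def filter_expressed(
    matrix: pd.DataFrame, min_reads: int = 5, strict_greater: bool = False
) -> pd.DataFrame:
    """Keep rows with evidence of expression in at least one sample.

    Default keeps rows whose maximum count is >= ``min_reads`` (at least
    five reads in one sample); ``strict_greater`` switches to a strict
    > ``min_reads`` threshold.
    """
    if matrix.empty:
        return matrix
    mx = matrix.max(axis=1)
    keep = mx > min_reads if strict_greater else mx >= min_reads
    return matrix.loc[keep]


def median_ratio_size_factors(matrix: pd.DataFrame) -> pd.Series:
    """DESeq-style median-of-ratios size factors.

    For each sample j, the size factor is the median over rows i (rows
    with a zero anywhere are excluded) of count_ij divided by row i's
    geometric mean across samples.  Factors are rescaled to geometric
    mean 1 so that normalization is idempotent.
    """
    vals = matrix.to_numpy(dtype=float)
    if vals.size == 0:
        raise ValueError(
            "no rows with all-positive counts; fall back to library-size scaling"
        )
    eligible = (vals > 0).all(axis=1)
    if not eligible.any():
        raise ValueError(
            "no rows with all-positive counts; fall back to library-size scaling"
        )
    sub = vals[eligible]
    log_geo = np.log(sub).mean(axis=1, keepdims=True)
    ratios = np.exp(np.log(sub) - log_geo)
    factors = np.median(ratios, axis=0)
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=matrix.columns)


def median_ratio_normalize(
    matrix: pd.DataFrame,
    samples: Optional[pd.DataFrame] = None,
    per_fraction: bool = True,
) -> tuple[pd.Series, pd.DataFrame, pd.DataFrame]:
    """Normalize a PAS x sample count matrix by the median-ratio method.

    When ``samples`` (with a ``fraction`` column) is given and
    ``per_fraction`` is set, size factors are estimated within each
    fraction type (total / 4sU / FT libraries have grossly different
    compositions); otherwise globally.

    Returns ``(size_factors, normalized, rpm)`` where ``normalized`` is
    count / size_factor and ``rpm`` rescales each sample to reads per
    million of its normalized total.
    """
    if matrix.empty:
        raise ValueError("empty count matrix; nothing to normalize")
    if samples is not None and per_fraction:
        factors = pd.Series(index=matrix.columns, dtype=float)
        for _frac, grp in samples.groupby("fraction"):
            cols = [c for c in matrix.columns if c in grp.index]
            if cols:
                factors[cols] = median_ratio_size_factors(matrix[cols])
    else:
        factors = median_ratio_size_factors(matrix)
    normalized = matrix / factors
    totals = normalized.sum(axis=0)
    rpm = normalized / totals * 1e6
    return factors, normalized, rpm
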