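"""Dynamic vs static gene classification over a time course.

A gene is called *dynamic* when (i) a chi-squared statistic over its linear-
scale per-time-point means,

    chi2 = sum_i (Xi_bar - X_bar)^2 / X_bar,   df = n - 1,

with Benjamini–Hochberg adjusted p below ``alpha`` (default 0.01), and (ii)
its linear max/min fold change across time-point means strictly exceeds
``fc_cut`` (default 2).  The statistic is a variance-to-mean dispersion test
and presumes a positive, ratio-scale intensity, so log2 input is
exponentiated before either quantity is computed.  Note chi2 scales linearly
with overall intensity; this scale dependence is inherent to the statistic.

Also provides the 0–1 display normalization x -> (x - min)/(max - min).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .matrix import TimeCourseMatrix

__all__ = [
    "DynamicTestResult",
    "normalize01",
    "chi_squared_timepoint_stat",
    "fold_change",
    "classify_dynamic",
    "count_updown_by_timepoint",
    "DegenerateRangeError",
]


class DegenerateRangeError(ValueError):
    """0–1 normalization of a constant vector (max == min)."""


def normalize01(x) -> np.ndarray:
    """Map a vector affinely onto [0, 1]: (x - min) / (max - min)."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 values")
    lo, hi = x.min(), x.max()
    if hi == lo:
        raise DegenerateRangeError("constant vector: max equals min")
    return (x - lo) / (hi - lo)


def chi_squared_timepoint_stat(means):
    """Dispersion chi-squared over linear-scale per-time-point means.

    Returns ``(chi2, df, p_raw)`` with chi2 = Σ(Xi − X̄)²/X̄, X̄ the mean of
    the per-time-point means, df = n − 1 and p the upper-tail chi-squared
    probability.
    """
    means = np.asarray(means, dtype=float)
    if means.ndim != 1 or means.size < 2:
        raise ValueError("need >= 2 per-time-point means")
    xbar = means.mean()
    if xbar <= 0:
        raise ValueError("overall mean must be positive (linear scale required)")
    chi2 = float(np.sum((means - xbar) ** 2) / xbar)
    df = means.size - 1
    return chi2, df, float(stats.chi2.sf(chi2, df))


def fold_change(means, scale: str = "linear") -> float:
    """Linear max/min ratio of per-time-point means (log2 input is exponentiated)."""
    means = np.asarray(means, dtype=float)
    if scale == "log2":
        means = 2.0**means
    elif scale != "linear":
        raise ValueError("scale must be 'linear' or 'log2'")
    if (means <= 0).any():
        raise ValueError("linear-scale means must be positive")
    return float(means.max() / means.min())


@dataclass
class DynamicTestResult:
    """Per-gene classification table plus the overall dynamic fraction."""

    table: pd.DataFrame  # columns: chi2, df, p_raw, p_adj, fold_change, is_dynamic
    alpha: float
    fc_cut: float

    @property
    def dynamic_fraction(self) -> float:
        return float(self.table["is_dynamic"].mean())

    @property
    def dynamic_ids(self) -> list:
        return list(self.table.index[self.table["is_dynamic"]])


def classify_dynamic(
    matrix: TimeCourseMatrix, alpha: float = 0.01, fc_cut: float = 2.0
) -> DynamicTestResult:
    """Apply the chi-squared + fold-change filter to every gene.

    p-values are Benjamini–Hochberg adjusted jointly over all genes;
    ``is_dynamic`` requires BOTH ``p_adj < alpha`` AND ``fold_change > fc_cut``
    (both strict).
    """
    lin_means = matrix.timepoint_means(log2=False).to_numpy()
    n_t = lin_means.shape[1]
    xbar = lin_means.mean(axis=1)
    if (xbar <= 0).any():
        raise ValueError("non-positive linear mean encountered")
    chi2 = ((lin_means - xbar[:, None]) ** 2).sum(axis=1) / xbar
    df = n_t - 1
    p_raw = stats.chi2.sf(chi2, df)
    p_adj = multipletests(p_raw, method="fdr_bh")[1]
    fc = lin_means.max(axis=1) / lin_means.min(axis=1)
    table = pd.DataFrame(
        {
            "chi2": chi2,
            "df": df,
            "p_raw": p_raw,
            "p_adj": p_adj,
            "fold_change": fc,
            "is_dynamic": (p_adj < alpha) & (fc > fc_cut),
        },
        index=matrix.gene_ids,
    )
    return DynamicTestResult(table=table, alpha=alpha, fc_cut=fc_cut)


def count_updown_by_timepoint(
    result: DynamicTestResult, matrix: TimeCourseMatrix, margin: float = 0.5
) -> pd.DataFrame:
    """Per-time-point counts of dynamic genes enriched above/below baseline.

    Each dynamic gene's per-time-point log2 mean profile is standardized
    (mean 0, sd 1 across time-points); the gene counts as *up* at time-points
    where the standardized value exceeds ``margin`` (in sd units) and *down*
    where it falls below ``-margin``.
    """
    dyn = result.dynamic_ids
    counts = pd.DataFrame(
        0, index=pd.Index(matrix.time_order, name="time_point"), columns=["up", "down"]
    )
    if not dyn:
        return counts
    prof = matrix.timepoint_means(log2=True).loc[dyn].to_numpy()
    sd = prof.std(axis=1, ddof=1)
    keep = sd > 0
    z = (prof[keep] - prof[keep].mean(axis=1, keepdims=True)) / sd[keep, None]
    counts["up"] = (z > margin).sum(axis=0)
    counts["down"] = (z < -margin).sum(axis=0)
    return counts
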