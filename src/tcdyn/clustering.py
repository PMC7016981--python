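"""Soft clustering of standardized temporal profiles into expression patterns.

Dynamic genes are reduced to per-time-point mean profiles, z-scored across
time-points (Euclidean-space standardization), and soft-clustered with fuzzy
c-means using a low fuzzifier (m = 1.25, close to hard k-means but retaining
graded memberships).  A gene joins a pattern only when its largest membership
reaches the 0.5 threshold, so at most one pattern can claim it.  The number
of patterns is chosen as the largest c for which all pairwise centroid
Pearson correlations stay below an overlap ceiling (non-overlapping
patterns), and each pattern is classified by peak position(s), direction and
modality (unimodal vs bimodal).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .matrix import TimeCourseMatrix

__all__ = [
    "StandardizedProfile",
    "PatternModel",
    "standardize_profiles",
    "fuzzy_cmeans",
    "select_cluster_number",
    "ClusterNumberResult",
    "assign_patterns",
    "summarize_patterns",
]

UNASSIGNED = -1


@dataclass
class StandardizedProfile:
    """Per-gene z-scored mean profiles (rows: mean 0, sd 1 across time-points)."""

    profiles: pd.DataFrame  # genes × time-points
    dropped: list = field(default_factory=list)  # (gene_id, reason)

    @property
    def X(self) -> np.ndarray:
        return self.profiles.to_numpy()


@dataclass
class PatternModel:
    c: int
    m: float
    centroids: np.ndarray  # c × n_timepoints
    U: pd.DataFrame  # genes × clusters
    assignments: pd.Series  # cluster index or UNASSIGNED
    objective: float
    objective_history: list
    converged: bool
    ties: list = field(default_factory=list)
    time_points: list | None = None


def standardize_profiles(matrix: TimeCourseMatrix, dynamic_ids) -> StandardizedProfile:
    """Z-score each gene's per-time-point log2 mean profile across time-points.

    Genes with zero variance across time-points cannot be standardized and
    are dropped with a recorded reason.
    """
    dynamic_ids = list(dynamic_ids)
    if not dynamic_ids:
        raise ValueError("dynamic_ids is empty")
    prof = matrix.timepoint_means(log2=True).loc[dynamic_ids]
    sd = prof.std(axis=1, ddof=1)
    dropped = [(g, "zero variance across time-points") for g in prof.index[sd == 0]]
    keep = prof.index[sd > 0]
    if keep.empty:
        raise ValueError("all genes have zero variance across time-points")
    z = prof.loc[keep].sub(prof.loc[keep].mean(axis=1), axis=0).div(sd[keep], axis=0)
    return StandardizedProfile(profiles=z, dropped=dropped)


def _memberships(D2: np.ndarray, m: float) -> np.ndarray:
    """FCM membership update from squared distances; zero distance gives a
    crisp membership on the (first) coincident centroid."""
    zero = D2 <= 0
    with np.errstate(divide="ignore"):
        w = D2 ** (-1.0 / (m - 1.0))
    U = np.empty_like(D2)
    finite = ~zero.any(axis=1)
    U[finite] = w[finite] / w[finite].sum(axis=1, keepdims=True)
    for i in np.flatnonzero(~finite):
        U[i] = 0.0
        U[i, np.argmax(zero[i])] = 1.0
    return U


def _fcm_once(X: np.ndarray, c: int, m: float, tol: float, max_iter: int, rng):
    n = X.shape[0]
    centroids = X[rng.choice(n, size=c, replace=False)].copy()
    prev_obj = np.inf
    history: list = []
    converged = False
    U = None
    for _ in range(max_iter):
        D2 = cdist(X, centroids, metric="sqeuclidean")
        U = _memberships(D2, m)
        obj = float((U**m * D2).sum())
        # alternating minimization: non-increasing up to round-off
        assert obj <= prev_obj * (1 + 1e-9) + 1e-12, "FCM objective increased"
        history.append(obj)
        if prev_obj - obj < tol:
            converged = True
            break
        prev_obj = obj
        Um = U**m
        centroids = (Um.T @ X) / Um.sum(axis=0)[:, None]
    return centroids, U, history, converged


def fuzzy_cmeans(
    X: StandardizedProfile,
    c: int,
    m: float = 1.25,
    tol: float = 1e-6,
    max_iter: int = 1000,
    restarts: int = 10,
    seed: int = 0,
    membership_threshold: float = 0.5,
) -> PatternModel:
    """Fuzzy c-means on standardized profiles; best of ``restarts`` seeded
    random initializations (centroids drawn from data rows) by final objective.
    """
    data = X.X
    n = data.shape[0]
    if c < 2:
        raise ValueError("c must be >= 2")
    if c >= n:
        raise ValueError(f"c = {c} must be smaller than the number of genes ({n})")
    if m <= 1:
        raise ValueError("fuzzifier m must be > 1")
    best = None
    for r in range(restarts):
        rng = np.random.default_rng([int(seed), c, r])
        out = _fcm_once(data, c, m, tol, max_iter, rng)
        if best is None or out[2][-1] < best[2][-1]:
            best = out
    centroids, U, history, converged = best
    Udf = pd.DataFrame(U, index=X.profiles.index, columns=range(c))
    assignments, ties = assign_patterns(Udf, threshold=membership_threshold, return_ties=True)
    return PatternModel(
        c=c,
        m=m,
        centroids=centroids,
        U=Udf,
        assignments=assignments,
        objective=history[-1],
        objective_history=history,
        converged=converged,
        ties=ties,
        time_points=list(X.profiles.columns),
    )


@dataclass
class ClusterNumberResult:
    optimal_c: int
    model: PatternModel
    max_centroid_r: dict  # c -> max pairwise centroid Pearson r
    overlap_warning: bool = False


def _max_pairwise_r(centroids: np.ndarray) -> float:
    with np.errstate(invalid="ignore"):
        R = np.corrcoef(centroids)
    iu = np.triu_indices_from(R, k=1)
    vals = R[iu]
    vals = vals[np.isfinite(vals)]  # flat centroid: undefined r, cannot overlap
    return float(vals.max()) if vals.size else -1.0


def select_cluster_number(
    X: StandardizedProfile,
    c_range=range(2, 21),
    m: float = 1.25,
    overlap_r: float = 0.9,
    seed: int = 0,
    **fcm_kwargs,
) -> ClusterNumberResult:
    """Largest c whose fitted centroids are pairwise non-overlapping
    (all pairwise Pearson r < ``overlap_r``); scans ascending, stops at the
    first violation.  A violation already at the smallest c returns it with
    ``overlap_warning`` set.
    """
    cs = sorted(c_range)
    if not cs:
        raise ValueError("empty c_range")
    max_r: dict = {}
    last_ok = None
    for c in cs:
        model = fuzzy_cmeans(X, c, m=m, seed=seed, **fcm_kwargs)
        r = _max_pairwise_r(model.centroids)
        max_r[c] = r
        if r >= overlap_r:
            if last_ok is None:
                return ClusterNumberResult(c, model, max_r, overlap_warning=True)
            return ClusterNumberResult(last_ok[0], last_ok[1], max_r)
        last_ok = (c, model)
    return ClusterNumberResult(last_ok[0], last_ok[1], max_r)


def assign_patterns(U: pd.DataFrame, threshold: float = 0.5, return_ties: bool = False):
    """Assign each gene to its argmax cluster iff max membership >= threshold.

    Exact ties at the maximum are broken by the lower cluster index and
    recorded.  Unassigned genes get :data:`UNASSIGNED`.
    """
    arr = U.to_numpy()
    top = arr.max(axis=1)
    # np.argmax already takes the lowest index on ties
    argmax = arr.argmax(axis=1)
    assigned = np.where(top >= threshold, argmax, UNASSIGNED)
    ties = [
        (U.index[i], list(np.flatnonzero(arr[i] == top[i])))
        for i in range(arr.shape[0])
        if top[i] >= threshold and (arr[i] == top[i]).sum() > 1
    ]
    series = pd.Series(assigned, index=U.index, name="pattern")
    return (series, ties) if return_ties else series


def _strict_local_extrema(v: np.ndarray):
    """Indices of strict local maxima and minima (endpoints compare only the
    inner neighbour; plateaus are not extrema)."""
    n = len(v)
    maxima, minima = [], []
    for i in range(n):
        left = v[i - 1] if i > 0 else None
        right = v[i + 1] if i < n - 1 else None
        gt = all(v[i] > x for x in (left, right) if x is not None)
        lt = all(v[i] < x for x in (left, right) if x is not None)
        if gt:
            maxima.append(i)
        if lt:
            minima.append(i)
    return maxima, minima


def summarize_patterns(
    model: PatternModel, time_points=None, margin: float = 0.5
) -> pd.DataFrame:
    """Per-cluster shape taxonomy from the centroid (in sd units).

    Peaks are strict local maxima above ``margin`` (up) or minima below
    ``-margin`` (down); direction follows the sign of the dominant peak;
    one peak is unimodal, two or more bimodal; no peak yields a ``flat``
    warning label.
    """
    time_points = list(time_points) if time_points is not None else model.time_points
    rows = []
    counts = model.assignments.value_counts()
    for k in range(model.c):
        cent = model.centroids[k]
        maxima, minima = _strict_local_extrema(cent)
        up_peaks = [i for i in maxima if cent[i] > margin]
        down_peaks = [i for i in minima if cent[i] < -margin]
        peaks = sorted(up_peaks + down_peaks)
        if not peaks:
            direction, kind = "flat", "flat"
        else:
            dominant = max(peaks, key=lambda i: abs(cent[i]))
            direction = "up" if cent[dominant] > 0 else "down"
            kind = "unimodal" if len(peaks) == 1 else "bimodal"
        rows.append(
            {
                "cluster": k,
                "peak_positions": [p + 1 for p in peaks],
                "peak_time_points": [time_points[p] for p in peaks] if time_points else None,
                "direction": direction,
                "kind": kind,
                "n_assigned": int(counts.get(k, 0)),
            }
        )
    return pd.DataFrame(rows).set_index("cluster")
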