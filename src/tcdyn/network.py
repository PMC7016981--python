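"""Weighted coexpression networks and hub genes within expression patterns.

For the genes of one temporal expression pattern, an unsigned weighted
network is built on replicate-level expression: adjacency A_ij = |r_ij|^beta
with the soft power beta chosen as the smallest power whose connectivity
distribution approximates scale-free topology (signed R^2 of the log-log
degree fit >= 0.8, WGCNA-style), falling back to the conventional beta = 6.
From A come the topological overlap matrix (TOM), per-gene intramodular
connectivity kWithin (row sums over the pattern), and the module eigengene
(first principal component of the standardized member expression) with
per-gene membership kME.  Hubs are the top 10% most connected genes of the
pattern (ceiling rule; kWithin ties broken by kME, then stable id order).
No module-detection step is run: each expression pattern is one module.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "NetworkModel",
    "SoftPowerResult",
    "HubOverlapResult",
    "pick_soft_power",
    "adjacency",
    "topological_overlap",
    "intramodular_connectivity",
    "module_eigengene",
    "select_hubs",
    "hub_overlap_stats",
    "build_network",
]

logger = logging.getLogger(__name__)


def adjacency(X: pd.DataFrame, beta: float) -> pd.DataFrame:
    """Unsigned adjacency |Pearson r|^beta with zero diagonal.

    ``X`` is genes × samples (replicate-level).  Zero-variance genes get all
    their correlations set to 0 and are flagged in ``A.attrs['zero_variance']``.
    """
    if X.shape[0] < 2 or X.shape[1] < 3:
        raise ValueError("need >= 2 genes and >= 3 samples")
    arr = X.to_numpy(dtype=float)
    sd = arr.std(axis=1)
    flagged = list(X.index[sd == 0])
    if flagged:
        logger.warning("zero-variance genes in adjacency: %s", flagged[:5])
    with np.errstate(invalid="ignore", divide="ignore"):
        R = np.corrcoef(arr)
    R = np.nan_to_num(R, nan=0.0)
    A = np.abs(np.clip(R, -1.0, 1.0)) ** beta
    np.fill_diagonal(A, 0.0)
    out = pd.DataFrame(A, index=X.index, columns=X.index)
    out.attrs["zero_variance"] = flagged
    return out


def scale_free_fit(k: np.ndarray, n_bins: int = 10) -> float:
    """Signed R^2 of the log10 p(k) ~ log10 k regression over equal-width
    bins of log10(k); negated when the slope is positive (a genuinely
    scale-free network has a decreasing degree distribution)."""
    k = np.asarray(k, dtype=float)
    k = k[k > 0]
    if k.size < 3 or np.ptp(np.log10(k)) == 0:
        return -1.0
    logk = np.log10(k)
    edges = np.linspace(logk.min(), logk.max(), n_bins + 1)
    idx = np.clip(np.digitize(logk, edges[1:-1]), 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        mask = idx == b
        if not mask.any():
            continue
        xs.append(np.log10(10 ** logk[mask].mean()))
        ys.append(np.log10(mask.mean()))
    if len(xs) < 3:
        return -1.0
    fit = stats.linregress(xs, ys)
    r2 = float(fit.rvalue**2)
    return r2 if fit.slope <= 0 else -r2


@dataclass
class SoftPowerResult:
    beta: int
    fit_table: pd.DataFrame  # power -> scale-free fit, mean k
    fallback: bool = False


def pick_soft_power(
    X: pd.DataFrame,
    powers=range(1, 21),
    r2_target: float = 0.8,
    fallback_beta: int = 6,
) -> SoftPowerResult:
    """Smallest soft-threshold power whose network approximates scale-free
    topology (fit >= ``r2_target``); conventional fallback when none does."""
    if X.shape[0] < 20:
        raise ValueError(f"need >= 20 genes to assess scale-free topology, got {X.shape[0]}")
    powers = list(powers)
    if r2_target <= 0:
        # degenerate threshold: every power trivially qualifies
        return SoftPowerResult(beta=int(min(powers)), fit_table=pd.DataFrame())
    rows = []
    chosen = None
    for beta in powers:
        A = adjacency(X, beta)
        k = A.to_numpy().sum(axis=1)
        fit = scale_free_fit(k)
        rows.append({"power": beta, "fit": fit, "mean_k": float(k.mean())})
        if chosen is None and fit >= r2_target:
            chosen = int(beta)
    table = pd.DataFrame(rows).set_index("power")
    if chosen is None:
        warnings.warn(
            f"no power reached scale-free fit {r2_target}; falling back to beta = {fallback_beta}",
            UserWarning,
            stacklevel=2,
        )
        return SoftPowerResult(beta=int(fallback_beta), fit_table=table, fallback=True)
    return SoftPowerResult(beta=chosen, fit_table=table)


def topological_overlap(A: pd.DataFrame) -> pd.DataFrame:
    """TOM_ij = (Σ_u A_iu A_uj + A_ij) / (min(k_i, k_j) + 1 − A_ij), diag 1."""
    arr = A.to_numpy(dtype=float)
    k = arr.sum(axis=1)
    num = arr @ arr + arr
    den = np.minimum.outer(k, k) + 1.0 - arr
    tom = num / den
    np.fill_diagonal(tom, 1.0)
    return pd.DataFrame(tom, index=A.index, columns=A.columns)


def intramodular_connectivity(A: pd.DataFrame, members) -> pd.Series:
    """kWithin_i = Σ_{j in members, j≠i} A_ij for each member gene."""
    members = list(members)
    missing = [g for g in members if g not in A.index]
    if missing:
        raise KeyError(f"members absent from adjacency: {missing[:5]}")
    sub = A.loc[members, members]
    return sub.sum(axis=1).rename("kWithin")  # diagonal is 0 by construction


def module_eigengene(X_members: pd.DataFrame):
    """First principal component of the standardized member expression.

    Returns ``(eigengene, kME)``: the per-sample eigengene scores, sign-
    oriented to correlate positively with the mean member profile, and each
    member's Pearson correlation with it.
    """
    if X_members.shape[0] < 2:
        raise ValueError("need >= 2 member genes")
    arr = X_members.to_numpy(dtype=float)
    sd = arr.std(axis=1, ddof=1)
    keep = sd > 0
    Z = (arr[keep] - arr[keep].mean(axis=1, keepdims=True)) / sd[keep, None]
    if Z.size == 0 or np.allclose(Z, 0):
        raise ValueError("degenerate (rank-0) member matrix")
    _, s, Vt = np.linalg.svd(Z, full_matrices=False)
    if s[0] == 0:
        raise ValueError("degenerate (rank-0) member matrix")
    eig = Vt[0]
    mean_profile = Z.mean(axis=0)
    if np.corrcoef(eig, mean_profile)[0, 1] < 0:
        eig = -eig
    eigengene = pd.Series(eig, index=X_members.columns, name="eigengene")
    with np.errstate(invalid="ignore"):
        kme_vals = [
            np.corrcoef(row, eig)[0, 1] if row.std() > 0 else np.nan
            for row in arr
        ]
    kME = pd.Series(kme_vals, index=X_members.index, name="kME")
    return eigengene, kME


def select_hubs(kWithin: pd.Series, fraction: float = 0.10, kME: pd.Series | None = None) -> list:
    """Top ``ceil(fraction × n)`` genes by kWithin (ties by higher kME, then
    stable id order) — the pattern's hub set."""
    if len(kWithin) == 0:
        raise ValueError("empty pattern")
    n_hubs = math.ceil(fraction * len(kWithin))
    tbl = pd.DataFrame({"kWithin": kWithin})
    tbl["kME"] = kME.reindex(kWithin.index) if kME is not None else 0.0
    tbl = tbl.sort_values(["kWithin", "kME"], ascending=False, kind="stable")
    return list(tbl.index[:n_hubs])


@dataclass
class HubOverlapResult:
    observed_percent: float
    random_percents: np.ndarray
    random_mean: float


def hub_overlap_stats(
    hubs, reference_lists, universe, n_random: int = 50, seed: int = 0
) -> HubOverlapResult:
    """Percentage of hubs found in the union of the reference lists, with a
    control distribution from ``n_random`` uniform draws of |hubs| genes."""
    hubs = list(hubs)
    if not hubs:
        raise ValueError("empty hub set")
    universe = list(universe)
    uni = set(universe)
    reference = set()
    for lst in reference_lists:
        out = [g for g in lst if g not in uni]
        if out:
            raise ValueError(f"reference genes outside the universe: {out[:5]}")
        reference.update(lst)
    observed = 100.0 * len(reference.intersection(hubs)) / len(hubs)
    rng = np.random.default_rng(seed)
    draws = np.array(
        [
            100.0 * len(reference.intersection(rng.choice(universe, size=len(hubs), replace=False)))
            / len(hubs)
            for _ in range(n_random)
        ]
    )
    return HubOverlapResult(
        observed_percent=observed, random_percents=draws, random_mean=float(draws.mean())
    )


@dataclass
class NetworkModel:
    """One weighted network per expression pattern (the pattern is the module)."""

    beta: int
    A: pd.DataFrame
    TOM: pd.DataFrame
    kWithin: pd.Series
    eigengene: pd.Series
    kME: pd.Series
    hubs: list
    scalefree_R2: float
    fallback_beta: bool = False


def build_network(
    X_members: pd.DataFrame,
    beta: int | None = None,
    powers=range(1, 21),
    r2_target: float = 0.8,
    hub_fraction: float = 0.10,
) -> NetworkModel:
    """Full per-pattern network: soft power, adjacency, TOM, kWithin,
    eigengene/kME and the hub set."""
    fallback = False
    if beta is None:
        pick = pick_soft_power(X_members, powers=powers, r2_target=r2_target)
        beta, fallback = pick.beta, pick.fallback
        fit_at_beta = float(pick.fit_table.loc[beta, "fit"])
    else:
        A1 = adjacency(X_members, beta)
        fit_at_beta = scale_free_fit(A1.to_numpy().sum(axis=1))
    A = adjacency(X_members, beta)
    tom = topological_overlap(A)
    kwithin = intramodular_connectivity(A, A.index)
    eigengene, kme = module_eigengene(X_members)
    hubs = select_hubs(kwithin, fraction=hub_fraction, kME=kme)
    # invariants asserted on every build
    arr_a, arr_t = A.to_numpy(), tom.to_numpy()
    assert np.allclose(arr_a, arr_a.T) and (arr_a >= 0).all() and (arr_a <= 1).all()
    assert np.allclose(arr_t, arr_t.T) and (arr_t >= -1e-12).all() and (arr_t <= 1 + 1e-12).all()
    return NetworkModel(
        beta=int(beta),
        A=A,
        TOM=tom,
        kWithin=kwithin,
        eigengene=eigengene,
        kME=kme,
        hubs=hubs,
        scalefree_R2=fit_at_beta,
        fallback_beta=fallback,
    )
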