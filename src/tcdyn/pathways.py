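"""Single-sample gene-set enrichment time courses and coregulation clusters.

For every gene signature and sample, a single-sample enrichment score (ES) is
computed as a rank-weighted ECDF difference: genes are ranked by expression
within the sample, and the score accumulates the gap between the weighted
in-set cumulative distribution (rank weight r^alpha, alpha = 0.25) and the
unweighted out-of-set cumulative distribution.  The ES depends on ranks only,
so it is invariant to monotone transforms of the expression values.

Signature time courses are then correlated pairwise (Pearson over per-sample
scores); signatures form a *coregulation cluster* when every pairwise
correlation within the group is significant and positive — i.e. the group is
a clique in the significance graph.  Disjoint clusters are reported by greedy
extraction of the largest maximal clique.  Per-time-point cluster enrichment
is summarized as mean ± SEM of member scores with a Mann–Whitney test of the
time-point's scores against all other time-points pooled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .dynamics import DegenerateRangeError, normalize01
from .matrix import TimeCourseMatrix

__all__ = [
    "GeneSetCollection",
    "EnrichmentTrack",
    "CorrelationMatrix",
    "CoregulationCluster",
    "read_gmt",
    "write_gmt",
    "ssgsea_score",
    "enrichment_timecourse",
    "signature_correlation",
    "find_coregulation_clusters",
    "cluster_timepoint_enrichment",
]

logger = logging.getLogger(__name__)


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT semantics)."""

    sets: dict  # name -> list of gene ids
    source: str = ""

    def __post_init__(self) -> None:
        empty = [n for n, members in self.sets.items() if not members]
        if empty:
            raise ValueError(f"empty gene sets: {empty}")

    def __len__(self) -> int:
        return len(self.sets)

    def restrict_to(self, universe) -> tuple["GeneSetCollection", dict]:
        """Intersect every set with the expression universe; dropped members
        are returned (and logged) per set."""
        universe = set(universe)
        kept, dropped = {}, {}
        for name, members in self.sets.items():
            inside = [g for g in members if g in universe]
            out = [g for g in members if g not in universe]
            if out:
                dropped[name] = out
                logger.info("set %s: dropped %d members outside universe", name, len(out))
            if inside:
                kept[name] = inside
        return GeneSetCollection(sets=kept, source=self.source), dropped


def read_gmt(path) -> GeneSetCollection:
    """Parse a GMT file (tab-separated: name, description, members...)."""
    sets = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}:{ln}: GMT line needs name, description and >=1 member")
        name = parts[0]
        if name in sets:
            raise ValueError(f"{path}:{ln}: duplicate set name {name!r}")
        sets[name] = [g for g in parts[2:] if g]
    return GeneSetCollection(sets=sets, source=str(path))


def write_gmt(collection: GeneSetCollection, path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, members in collection.sets.items():
            fh.write("\t".join([name, description, *members]) + "\n")


def ssgsea_score(sample_column: pd.Series, gene_set, alpha_weight: float = 0.25) -> float:
    """Single-sample enrichment score of one gene set in one sample.

    Genes are ranked by expression descending (rank N for the top gene, ties
    kept in stable input order); with in-set rank weights r^alpha the score is

        ES = Σ_positions ( cum Σ_in-set r^α / Σ_in-set r^α
                           − cum count_out-of-set / N_out ).
    """
    values = np.asarray(sample_column, dtype=float)
    genes = list(sample_column.index)
    n = len(genes)
    in_set = np.fromiter((g in set(gene_set) for g in genes), dtype=bool, count=n)
    n_in = int(in_set.sum())
    if n_in < 2:
        raise ValueError(f"gene set has {n_in} member(s) in the expression universe (need >= 2)")
    if n_in == n:
        raise ValueError("gene set equals the universe; out-of-set ECDF undefined")
    order = np.argsort(-values, kind="stable")
    if np.unique(values).size < n:
        logger.debug("expression ties present; broken by stable input order")
    ranks = np.arange(n, 0, -1, dtype=float)  # rank N at top position
    in_ordered = in_set[order]
    w = np.where(in_ordered, ranks**alpha_weight, 0.0)
    p_in = np.cumsum(w) / w.sum()
    p_out = np.cumsum(~in_ordered) / float(n - n_in)
    return float(np.sum(p_in - p_out))


@dataclass
class EnrichmentTrack:
    """Signature × sample enrichment scores.

    ``ES`` holds raw scores, ``ES01`` the per-signature 0–1 normalization
    across samples (display/plotting scale).
    """

    ES: pd.DataFrame
    ES01: pd.DataFrame
    alpha_weight: float
    errors: dict = field(default_factory=dict)  # set name -> message
    dropped_members: dict = field(default_factory=dict)


def enrichment_timecourse(
    matrix: TimeCourseMatrix, sets: GeneSetCollection, alpha_weight: float = 0.25
) -> EnrichmentTrack:
    """ES for every (signature, sample); per-set errors are collected and the
    run continues with the remaining sets."""
    restricted, dropped = sets.restrict_to(matrix.gene_ids)
    rows, errors = {}, {}
    missing = [n for n in sets.sets if n not in restricted.sets]
    for name in missing:
        errors[name] = "no members in the expression universe"
    for name, members in restricted.sets.items():
        try:
            rows[name] = [
                ssgsea_score(matrix.values[s], members, alpha_weight)
                for s in matrix.values.columns
            ]
        except ValueError as exc:
            errors[name] = str(exc)
    if not rows:
        raise ValueError("no scoreable gene sets")
    ES = pd.DataFrame(rows, index=matrix.values.columns).T
    es01 = {}
    for name, row in ES.iterrows():
        try:
            es01[name] = normalize01(row.to_numpy())
        except DegenerateRangeError:
            errors[name] = "constant enrichment track; 0-1 normalization undefined"
            es01[name] = np.full(len(row), np.nan)
    ES01 = pd.DataFrame(es01, index=ES.columns).T
    return EnrichmentTrack(
        ES=ES, ES01=ES01, alpha_weight=alpha_weight, errors=errors, dropped_members=dropped
    )


@dataclass
class CorrelationMatrix:
    r: pd.DataFrame
    p: pd.DataFrame
    n_obs: int
    excluded: list = field(default_factory=list)  # zero-variance signatures


def signature_correlation(
    track: EnrichmentTrack, matrix: TimeCourseMatrix | None = None, on: str = "samples"
) -> CorrelationMatrix:
    """Pairwise Pearson correlation of signature enrichment time courses.

    ``on='samples'`` (default) correlates per-sample scores for maximal
    statistical power; ``on='timepoint_means'`` correlates per-time-point
    mean scores instead (requires ``matrix`` for the design).  Two-sided
    p-values come from the t-transform of r.  Zero-variance signatures are
    flagged and excluded from downstream clustering.
    """
    X = track.ES
    if on == "timepoint_means":
        if matrix is None:
            raise ValueError("timepoint_means correlation needs the expression matrix design")
        X = pd.DataFrame(
            {t: X[matrix.samples_at(t)].mean(axis=1) for t in matrix.time_order}
        )
    elif on != "samples":
        raise ValueError("on must be 'samples' or 'timepoint_means'")
    n = X.shape[1]
    if n < 3:
        raise ValueError("need >= 3 observations for correlation p-values")
    arr = X.to_numpy()
    sd = arr.std(axis=1)
    excluded = list(X.index[sd == 0])
    with np.errstate(invalid="ignore", divide="ignore", over="ignore"):
        R = np.corrcoef(arr)
        R = np.clip(R, -1.0, 1.0)
        t = R * np.sqrt((n - 2) / np.maximum(1.0 - R**2, np.finfo(float).tiny))
        P = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    np.fill_diagonal(R, 1.0)
    np.fill_diagonal(P, 0.0)
    r = pd.DataFrame(R, index=X.index, columns=X.index)
    p = pd.DataFrame(P, index=X.index, columns=X.index)
    r.loc[excluded, :] = np.nan
    r.loc[:, excluded] = np.nan
    p.loc[excluded, :] = np.nan
    p.loc[:, excluded] = np.nan
    return CorrelationMatrix(r=r, p=p, n_obs=n, excluded=excluded)


@dataclass
class CoregulationCluster:
    members: list
    timecourse: pd.DataFrame | None = None  # filled by cluster_timepoint_enrichment


def find_coregulation_clusters(corr: CorrelationMatrix, p_cut: float = 0.05) -> list:
    """Disjoint groups of signatures in which *every* pairwise correlation is
    significant (p < ``p_cut``) and positive.

    The significance graph's maximal cliques are extracted greedily: largest
    clique first (ties by lexicographic member order), claimed signatures
    removed, repeated.  Singletons are not clusters.
    """
    names = [s for s in corr.r.index if s not in corr.excluded]
    G = nx.Graph()
    G.add_nodes_from(names)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            if corr.p.loc[a, b] < p_cut and corr.r.loc[a, b] > 0:
                G.add_edge(a, b)
    clusters = []
    while True:
        cliques = [sorted(c) for c in nx.find_cliques(G) if len(c) >= 2]
        if not cliques:
            break
        best = sorted(cliques, key=lambda c: (-len(c), tuple(c)))[0]
        clusters.append(CoregulationCluster(members=best))
        G.remove_nodes_from(best)
    return clusters


_STARS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


def _stars(p: float) -> str:
    for cut, s in _STARS:
        if p < cut:
            return s
    return ""


def cluster_timepoint_enrichment(
    track: EnrichmentTrack, clusters: list, matrix: TimeCourseMatrix
) -> dict:
    """Per-cluster, per-time-point summary of member enrichment.

    For each time-point: mean ± SEM of the member-signature per-sample ES01
    scores, and a two-sided Mann–Whitney U p-value of those scores against
    the member scores at all other time-points pooled (p reported as NaN when
    either side has fewer than 3 scores).  Significance stars at
    0.05 / 0.01 / 0.001.
    """
    if not clusters:
        raise ValueError("clusters is empty")
    out = {}
    for ci, cluster in enumerate(clusters):
        scores = track.ES01.loc[cluster.members]
        rows = []
        for t in matrix.time_order:
            here = scores[matrix.samples_at(t)].to_numpy().ravel()
            other_samples = [s for s in scores.columns if s not in matrix.samples_at(t)]
            there = scores[other_samples].to_numpy().ravel()
            here, there = here[np.isfinite(here)], there[np.isfinite(there)]
            if len(here) < 3 or len(there) < 3:
                p = np.nan
            else:
                p = float(stats.mannwhitneyu(here, there, alternative="two-sided").pvalue)
            rows.append(
                {
                    "time_point": t,
                    "mean": float(here.mean()) if len(here) else np.nan,
                    "sem": float(stats.sem(here)) if len(here) > 1 else np.nan,
                    "p": p,
                    "stars": _stars(p) if np.isfinite(p) else "",
                }
            )
        table = pd.DataFrame(rows).set_index("time_point")
        cluster.timecourse = table
        out[ci] = table
    return out
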