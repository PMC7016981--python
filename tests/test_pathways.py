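"""ssGSEA scoring, signature correlation, coregulation cliques, time-point tests."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tcdyn import (
    SimulationConfig,
    cluster_timepoint_enrichment,
    enrichment_timecourse,
    find_coregulation_clusters,
    generate_gene_sets,
    generate_timecourse,
    read_gmt,
    signature_correlation,
    ssgsea_score,
    write_gmt,
)
from tcdyn.pathways import CorrelationMatrix, EnrichmentTrack, GeneSetCollection


class TestGMT:
    def test_round_trip(self, tmp_path):
        coll = GeneSetCollection(sets={"A": ["g1", "g2"], "B": ["g3", "g4", "g5"]})
        path = tmp_path / "sets.gmt"
        write_gmt(coll, path)
        back = read_gmt(path)
        assert back.sets == coll.sets

    def test_malformed_line_rejected(self, tmp_path):
        path = tmp_path / "bad.gmt"
        path.write_text("onlyname\tdesc\n")
        with pytest.raises(ValueError, match="GMT"):
            read_gmt(path)

    def test_restrict_logs_dropped_members(self):
        coll = GeneSetCollection(sets={"A": ["g1", "gX"]})
        restricted, dropped = coll.restrict_to(["g1", "g2"])
        assert restricted.sets == {"A": ["g1"]}
        assert dropped == {"A": ["gX"]}


class TestSsgseaScore:
    def _expr(self, n=1000, seed=0):
        rng = np.random.default_rng(seed)
        return pd.Series(rng.normal(size=n), index=[f"g{i}" for i in range(n)])

    def test_top_set_beats_random_sets(self):
        x = self._expr()
        top = list(x.sort_values(ascending=False).index[:10])
        es_top = ssgsea_score(x, top)
        assert es_top > 0
        rng = np.random.default_rng(1)
        for _ in range(200):
            rand = list(rng.choice(x.index, size=10, replace=False))
            assert es_top >= ssgsea_score(x, rand)

    def test_bottom_set_is_negative(self):
        x = self._expr()
        bottom = list(x.sort_values().index[:10])
        assert ssgsea_score(x, bottom) < 0

    def test_reversing_ranks_flips_configuration(self):
        x = self._expr(n=200)
        top = list(x.sort_values(ascending=False).index[:10])
        assert ssgsea_score(x, top) > 0
        assert ssgsea_score(-x, top) < 0

    def test_rank_only_dependence(self):
        x = self._expr(n=300, seed=2)
        s = list(x.sort_values(ascending=False).index[10:30])
        monotone = np.exp(x / 3) + 7  # strictly increasing transform
        assert ssgsea_score(x, s) == pytest.approx(ssgsea_score(monotone, s))

    def test_bad_sets_rejected(self):
        x = self._expr(n=50)
        with pytest.raises(ValueError, match="member"):
            ssgsea_score(x, ["nope"])
        with pytest.raises(ValueError, match="universe"):
            ssgsea_score(x, list(x.index))


class TestEnrichmentTimecourse:
    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_aligned_signature_peaks_at_planted_timepoint(self, seed):
        cfg = SimulationConfig(n_static=800, n_dynamic=120, n_sets=1, set_size=20,
                               aligned_fraction=1.0, seed=seed)
        m, truth = generate_timecourse(cfg)
        sets = generate_gene_sets(truth, cfg, alignment=["up_t1"])
        track = enrichment_timecourse(m, sets)
        name = track.ES.index[0]
        t1_mean = track.ES.loc[name, m.samples_at(m.time_order[0])].mean()
        for t in m.time_order[1:]:
            assert t1_mean > track.ES.loc[name, m.samples_at(t)].mean()

    def test_duplicated_signature_gives_identical_rows(self, make_matrix):
        rng = np.random.default_rng(0)
        matrix = make_matrix({f"g{i}": rng.normal(6, 1, 6) for i in range(100)})
        sets = GeneSetCollection(sets={"A": [f"g{i}" for i in range(10)],
                                       "B": [f"g{i}" for i in range(10)]})
        track = enrichment_timecourse(matrix, sets)
        np.testing.assert_array_equal(track.ES.loc["A"], track.ES.loc["B"])

    def test_es01_spans_unit_interval(self, make_matrix):
        rng = np.random.default_rng(1)
        matrix = make_matrix({f"g{i}": rng.normal(6, 1, 6) for i in range(100)})
        sets = GeneSetCollection(sets={"A": [f"g{i}" for i in range(15)]})
        track = enrichment_timecourse(matrix, sets)
        assert track.ES01.loc["A"].min() == 0 and track.ES01.loc["A"].max() == 1

    def test_per_set_errors_collected_run_continues(self, make_matrix):
        rng = np.random.default_rng(2)
        matrix = make_matrix({f"g{i}": rng.normal(6, 1, 6) for i in range(50)})
        sets = GeneSetCollection(sets={"ok": [f"g{i}" for i in range(10)], "gone": ["zz1", "zz2"]})
        track = enrichment_timecourse(matrix, sets)
        assert "ok" in track.ES.index and "gone" in track.errors


class TestSignatureCorrelation:
    def _track(self, ES):
        return EnrichmentTrack(ES=ES, ES01=ES, alpha_weight=0.25)

    def test_self_and_negation(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=18)
        ES = pd.DataFrame({"s": list(range(18))}).T
        ES = pd.DataFrame([a, -a], index=["A", "negA"], columns=[f"c{i}" for i in range(18)])
        corr = signature_correlation(self._track(ES))
        assert corr.r.loc["A", "A"] == 1
        assert corr.r.loc["A", "negA"] == pytest.approx(-1)
        assert corr.n_obs == 18

    def test_independent_noise_rarely_significant(self):
        rng = np.random.default_rng(5)
        ES = pd.DataFrame(rng.normal(size=(200, 18)),
                          index=[f"s{i}" for i in range(200)],
                          columns=[f"c{i}" for i in range(18)])
        corr = signature_correlation(self._track(ES))
        ps = [corr.p.iloc[2 * i, 2 * i + 1] for i in range(100)]  # disjoint pairs
        assert np.mean([p > 0.05 for p in ps]) >= 0.9

    def test_zero_variance_signature_excluded(self):
        ES = pd.DataFrame([[1.0] * 18, list(range(18))], index=["flat", "ok"],
                          columns=[f"c{i}" for i in range(18)])
        corr = signature_correlation(self._track(ES))
        assert corr.excluded == ["flat"]
        assert np.isnan(corr.r.loc["flat", "ok"])


def exhaustive_greedy_cliques(names, edge):
    """Oracle: maximal cliques by subset enumeration, then the same greedy rule."""
    def is_clique(sub):
        return all(edge(a, b) for a, b in itertools.combinations(sub, 2))

    remaining = set(names)
    out = []
    while True:
        cliques = []
        for r in range(len(remaining), 1, -1):
            for sub in itertools.combinations(sorted(remaining), r):
                if is_clique(sub) and not any(
                    is_clique(tuple(sorted(set(sub) | {x}))) for x in remaining - set(sub)
                ):
                    cliques.append(list(sub))
        if not cliques:
            return out
        best = sorted(cliques, key=lambda c: (-len(c), tuple(c)))[0]
        out.append(best)
        remaining -= set(best)


def corr_from_graph(names, edges) -> CorrelationMatrix:
    r = pd.DataFrame(0.0, index=names, columns=names)
    p = pd.DataFrame(1.0, index=names, columns=names)
    for a, b in edges:
        r.loc[a, b] = r.loc[b, a] = 0.9
        p.loc[a, b] = p.loc[b, a] = 0.001
    np.fill_diagonal(r.values, 1.0)
    np.fill_diagonal(p.values, 0.0)
    return CorrelationMatrix(r=r, p=p, n_obs=18)


class TestCoregulationClusters:
    def test_triangle_is_one_cluster(self):
        corr = corr_from_graph(list("ABC"), [("A", "B"), ("B", "C"), ("A", "C")])
        clusters = find_coregulation_clusters(corr)
        assert [c.members for c in clusters] == [["A", "B", "C"]]

    def test_chain_yields_lexicographic_pair(self):
        corr = corr_from_graph(list("ABC"), [("A", "B"), ("B", "C")])
        clusters = find_coregulation_clusters(corr)
        assert [c.members for c in clusters] == [["A", "B"]]

    def test_no_significant_pairs_no_clusters(self):
        corr = corr_from_graph(list("ABC"), [])
        assert find_coregulation_clusters(corr) == []

    def test_negative_correlation_excluded_from_edges(self):
        corr = corr_from_graph(list("AB"), [("A", "B")])
        corr.r.loc["A", "B"] = corr.r.loc["B", "A"] = -0.9
        assert find_coregulation_clusters(corr) == []

    @pytest.mark.parametrize("seed", range(5))
    def test_greedy_matches_exhaustive_oracle_on_random_graphs(self, seed):
        rng = np.random.default_rng(seed)
        names = [f"s{i:02d}" for i in range(10)]
        edges = [
            (a, b) for a, b in itertools.combinations(names, 2) if rng.random() < 0.35
        ]
        corr = corr_from_graph(names, edges)
        got = [c.members for c in find_coregulation_clusters(corr)]
        eset = {frozenset(e) for e in edges}
        want = exhaustive_greedy_cliques(names, lambda a, b: frozenset((a, b)) in eset)
        assert got == want

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_planted_coregulation_recovered(self, seed):
        cfg = SimulationConfig(n_static=2000, n_dynamic=600, n_sets=15, set_size=25,
                               aligned_fraction=1.0, seed=seed)
        m, truth = generate_timecourse(cfg)
        sets = generate_gene_sets(truth, cfg, alignment=["up_t3"] * 5 + [None] * 10)
        track = enrichment_timecourse(m, sets)
        corr = signature_correlation(track)
        clusters = find_coregulation_clusters(corr)
        aligned = {n for n, a in truth.set_alignment.items() if a == "up_t3"}
        assert any(aligned <= set(c.members) for c in clusters)


def mannwhitney_u_by_pair_counting(x, y):
    """Oracle: exhaustive pair enumeration (ties count half)."""
    u = 0.0
    for xi in x:
        for yi in y:
            u += 1.0 if xi > yi else (0.5 if xi == yi else 0.0)
    return u


class TestClusterTimepointEnrichment:
    def test_u_statistic_matches_pair_counting_oracle(self):
        x = [3.1, 0.2, 5.5, 2.2]
        y = [1.0, 2.2, 4.4, 0.1, 2.0]
        u_scipy = stats.mannwhitneyu(x, y, alternative="two-sided").statistic
        assert u_scipy == mannwhitney_u_by_pair_counting(x, y)

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_aligned_cluster_significant_at_planted_timepoint(self, seed):
        cfg = SimulationConfig(n_static=800, n_dynamic=120, n_sets=3, set_size=20,
                               aligned_fraction=1.0, seed=seed)
        m, truth = generate_timecourse(cfg)
        sets = generate_gene_sets(truth, cfg, alignment=["up_t6"] * 3)
        track = enrichment_timecourse(m, sets)
        corr = signature_correlation(track)
        clusters = find_coregulation_clusters(corr)
        assert clusters
        tables = cluster_timepoint_enrichment(track, clusters, m)
        tbl = tables[0]
        t6 = m.time_order[5]
        assert tbl.loc[t6, "p"] < 0.05
        assert tbl.loc[t6, "mean"] > tbl["mean"].drop(t6).max()

    def test_identical_scores_give_p_one(self, make_matrix):
        matrix = make_matrix({f"g{i}": [6.0] * 6 for i in range(30)}, noise_sd=0.0)
        ES = pd.DataFrame([[0.5] * 18, [0.5] * 18], index=["A", "B"],
                          columns=matrix.values.columns)
        track = EnrichmentTrack(ES=ES, ES01=ES, alpha_weight=0.25)
        from tcdyn.pathways import CoregulationCluster

        tables = cluster_timepoint_enrichment(track, [CoregulationCluster(["A", "B"])], matrix)
        assert (tables[0]["p"].dropna() == 1.0).all()
        assert (tables[0]["stars"] == "").all()
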