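import itertools

import networkx as nx
import numpy as np
import pytest

from capipe.core import NetworkConfig, TraceMatrix, ValidationError
from capipe.network import (
    FunctionalNetwork,
    build_network,
    closeness_centrality,
    clustering_coefficient,
    degree_centrality,
    normalize_to_habituation,
    session_summary,
)


def _tm(values, fps=20.0):
    values = np.asarray(values, dtype=float)
    return TraceMatrix(values, tuple(str(i) for i in range(values.shape[0])), fps)


def _net_from_edges(n, edges):
    g = nx.Graph()
    g.add_nodes_from(str(i) for i in range(n))
    for i, j, w in edges:
        g.add_edge(str(i), str(j), weight=w)
    import pandas as pd

    return FunctionalNetwork(g, pd.DataFrame(columns=["cell_i", "cell_j", "r", "p_adjusted"]))


# ---- brute-force oracles -------------------------------------------------


def brute_degree(g):
    n = g.number_of_nodes()
    return {v: len(list(g[v])) / (n - 1) for v in g.nodes}


def brute_barrat(g):
    out = {}
    for i in g.nodes:
        neigh = list(g[i])
        k = len(neigh)
        if k < 2:
            out[i] = 0.0
            continue
        s = sum(g[i][j]["weight"] for j in neigh)
        total = 0.0
        for j, h in itertools.combinations(neigh, 2):
            if g.has_edge(j, h):
                total += (g[i][j]["weight"] + g[i][h]["weight"]) / 2
        out[i] = 2 * total / (s * (k - 1))
    return out


def brute_closeness(g):
    # Floyd-Warshall on 1/w lengths, averaged within components
    nodes = list(g.nodes)
    n = len(nodes)
    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0.0)
    pos = {v: i for i, v in enumerate(nodes)}
    for u, v, d in g.edges(data=True):
        dist[pos[u], pos[v]] = dist[pos[v], pos[u]] = 1.0 / d["weight"]
    for k in range(n):
        dist = np.minimum(dist, dist[:, [k]] + dist[[k], :])
    out = {}
    for v in nodes:
        row = dist[pos[v]]
        reachable = np.isfinite(row) & (row > 0)
        out[v] = reachable.sum() / row[reachable].sum() if reachable.any() else 0.0
    return out


# ---- build_network -------------------------------------------------------


class TestBuildNetwork:
    def test_comonotone_pair_weight_one(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=1000)
        net = build_network(_tm(np.vstack([x, np.exp(x)])))
        assert net.n_edges == 1
        assert net.edge_table["r"].iloc[0] == pytest.approx(1.0)

    def test_independent_noise_yields_no_edges(self):
        rng = np.random.default_rng(1)
        empties = 0
        for _ in range(5):
            net = build_network(_tm(rng.normal(size=(20, 6000))))
            empties += net.n_edges == 0
        assert empties == 5

    def test_three_cell_edge_set_matches_all_pairs_oracle(self):
        from scipy import stats

        rng = np.random.default_rng(2)
        base = rng.normal(size=2000)
        values = np.vstack(
            [base + rng.normal(0, 0.3, 2000), base + rng.normal(0, 0.3, 2000), rng.normal(size=2000)]
        )
        net = build_network(_tm(values))
        expected = set()
        for i, j in itertools.combinations(range(3), 2):
            r, p = stats.spearmanr(values[i], values[j])
            if min(p * 3, 1.0) < 0.001 and r > 0:
                expected.add((str(i), str(j)))
        assert {tuple(sorted(e)) for e in net.graph.edges} == expected

    def test_invariant_to_monotone_transforms(self):
        rng = np.random.default_rng(3)
        base = rng.normal(size=1500)
        values = np.vstack([base + rng.normal(0, 0.5, 1500) for _ in range(4)])
        net_a = build_network(_tm(values))
        transformed = np.vstack(
            [np.exp(values[0]), values[1] ** 3, 5 * values[2] - 2, np.arctan(values[3])]
        )
        net_b = build_network(_tm(transformed))
        assert set(net_a.graph.edges) == set(net_b.graph.edges)
        for u, v in net_a.graph.edges:
            assert net_a.graph[u][v]["weight"] == pytest.approx(net_b.graph[u][v]["weight"])

    def test_single_cell_rejected(self):
        with pytest.raises(ValidationError):
            build_network(_tm(np.random.default_rng(4).normal(size=(1, 100))))

    def test_constant_trace_node_kept_without_edges(self):
        rng = np.random.default_rng(5)
        values = np.vstack([np.full(500, 1.0), rng.normal(size=500), rng.normal(size=500)])
        with pytest.warns(UserWarning, match="constant"):
            net = build_network(_tm(values))
        assert "0" in net.graph.nodes
        assert net.graph.degree("0") == 0


# ---- centralities --------------------------------------------------------


class TestDegree:
    def test_complete_graph_all_one(self):
        net = _net_from_edges(5, [(i, j, 0.5) for i, j in itertools.combinations(range(5), 2)])
        assert all(v == pytest.approx(1.0) for v in degree_centrality(net).values())

    def test_isolated_node_zero(self):
        net = _net_from_edges(3, [(0, 1, 0.5)])
        assert degree_centrality(net)["2"] == 0.0

    def test_star_graph(self):
        net = _net_from_edges(4, [(0, 1, 0.5), (0, 2, 0.5), (0, 3, 0.5)])
        deg = degree_centrality(net)
        assert deg["0"] == pytest.approx(1.0)
        assert deg["1"] == pytest.approx(1 / 3)


class TestClustering:
    def test_equal_weight_triangle_all_one(self):
        net = _net_from_edges(3, [(0, 1, 0.4), (0, 2, 0.4), (1, 2, 0.4)])
        assert all(v == pytest.approx(1.0) for v in clustering_coefficient(net).values())

    def test_star_graph_all_zero(self):
        net = _net_from_edges(4, [(0, 1, 0.5), (0, 2, 0.5), (0, 3, 0.5)])
        assert all(v == 0.0 for v in clustering_coefficient(net).values())

    def test_weighted_four_node_fixture_matches_barrat_oracle(self):
        edges = [(0, 1, 0.9), (0, 2, 0.3), (1, 2, 0.6), (2, 3, 0.8)]
        net = _net_from_edges(4, edges)
        expected = brute_barrat(net.graph)
        got = clustering_coefficient(net)
        for v in got:
            assert got[v] == pytest.approx(expected[v], abs=1e-12)


class TestCloseness:
    def test_unit_weight_path(self):
        net = _net_from_edges(3, [(0, 1, 1.0), (1, 2, 1.0)])
        clo = closeness_centrality(net)
        assert clo["1"] == pytest.approx(1.0)
        assert clo["0"] == pytest.approx(2 / 3)

    def test_complete_unit_graph_all_one(self):
        net = _net_from_edges(4, [(i, j, 1.0) for i, j in itertools.combinations(range(4), 2)])
        assert all(v == pytest.approx(1.0) for v in closeness_centrality(net).values())

    def test_disconnected_dyads_scored_within_component(self):
        net = _net_from_edges(4, [(0, 1, 0.5), (2, 3, 0.25)])
        clo = closeness_centrality(net)
        assert clo["0"] == pytest.approx(0.5)  # distance 1/0.5 = 2, 1/2
        assert clo["2"] == pytest.approx(0.25)


class TestOracleEquivalence:
    def test_random_weighted_graphs_match_brute_force(self):
        rng = np.random.default_rng(6)
        for _ in range(200):
            n = int(rng.integers(2, 7))
            g = nx.Graph()
            g.add_nodes_from(str(i) for i in range(n))
            for i, j in itertools.combinations(range(n), 2):
                if rng.random() < 0.6:
                    g.add_edge(str(i), str(j), weight=float(rng.uniform(0.05, 1.0)))
            import pandas as pd

            net = FunctionalNetwork(g, pd.DataFrame())
            deg, clu, clo = degree_centrality(net), clustering_coefficient(net), closeness_centrality(net)
            b_deg, b_clu, b_clo = brute_degree(g), brute_barrat(g), brute_closeness(g)
            for v in g.nodes:
                assert deg[v] == pytest.approx(b_deg[v], abs=1e-12)
                assert clu[v] == pytest.approx(b_clu[v], abs=1e-12)
                assert clo[v] == pytest.approx(b_clo[v], abs=1e-12)


class TestNormalization:
    def test_identical_networks_100_percent(self):
        net = _net_from_edges(3, [(0, 1, 0.5), (1, 2, 0.5), (0, 2, 0.5)])
        s = session_summary(net)
        table = normalize_to_habituation({"HA": s, "S1": s})
        np.testing.assert_allclose(table["percent_of_HA"], 100.0)

    def test_doubled_mean_200_percent(self):
        s_ha = {"mean_degree": 0.2, "mean_clustering": 0.1, "mean_closeness": 0.3, "n_edges": 5}
        s_s1 = {"mean_degree": 0.4, "mean_clustering": 0.2, "mean_closeness": 0.6, "n_edges": 9}
        table = normalize_to_habituation({"HA": s_ha, "S1": s_s1})
        s1 = table[table.session == "S1"]
        np.testing.assert_allclose(s1["percent_of_HA"], 200.0)

    def test_zero_baseline_metric_yields_nan_percent(self):
        net = _net_from_edges(3, [(0, 1, 0.5), (1, 2, 0.5)])  # path: clustering 0
        s = session_summary(net)
        with pytest.warns(UserWarning, match="zero"):
            table = normalize_to_habituation({"HA": s, "S1": s})
        clus = table[table.metric == "mean_clustering"]
        assert clus["percent_of_HA"].isna().all()

    def test_missing_habituation_rejected(self):
        with pytest.raises(ValidationError):
            normalize_to_habituation({"S1": {"mean_degree": 1.0}})
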