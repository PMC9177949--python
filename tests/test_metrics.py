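"""Graph metrics against brute-force oracles, null-model behaviour, and AUC
aggregation."""

import networkx as nx
import numpy as np
import pytest

from _oracles import (
    oracle_betweenness,
    oracle_clustering,
    oracle_global_efficiency,
    oracle_local_efficiency,
    oracle_nodal_efficiency,
    oracle_nodal_local_efficiency,
    oracle_path_length,
    oracle_trapezoid,
    random_graph,
)
from conftest import graph_from_adjacency
from presbynet.metrics import (
    MetricError,
    characteristic_path_length,
    clustering_coefficient,
    connectivity_report,
    global_efficiency,
    global_metrics_over_grid,
    local_efficiency,
    metric_auc,
    nodal_metrics,
    random_reference_ensemble,
    small_world_indices,
)
from presbynet.network import ConnectivityMatrix, build_threshold_series, sparsity_grid


def complete(n):
    return graph_from_adjacency(np.ones((n, n)) - np.eye(n))


def star(n):
    adj = np.zeros((n, n))
    adj[0, 1:] = adj[1:, 0] = 1
    return graph_from_adjacency(adj)


def path_graph(n):
    adj = np.zeros((n, n))
    for i in range(n - 1):
        adj[i, i + 1] = adj[i + 1, i] = 1
    return graph_from_adjacency(adj)


class TestClustering:
    def test_complete_graph_is_fully_clustered(self):
        assert clustering_coefficient(complete(5)) == 1.0

    def test_star_has_no_triangles(self):
        assert clustering_coefficient(star(6)) == 0.0

    def test_toy_graph_matches_triangle_enumeration(self):
        adj = np.zeros((7, 7))
        for i, j in [(0, 1), (1, 2), (0, 2), (2, 3), (3, 4), (4, 5), (5, 3), (5, 6)]:
            adj[i, j] = adj[j, i] = 1
        g = graph_from_adjacency(adj)
        assert abs(clustering_coefficient(g) - oracle_clustering(adj)) < 1e-12


class TestPathLength:
    def test_complete_graph(self):
        assert characteristic_path_length(complete(6)) == 1.0

    def test_path_on_four_nodes(self):
        assert abs(characteristic_path_length(path_graph(4)) - 10.0 / 6.0) < 1e-12

    def test_disconnected_components_flagged(self):
        adj = np.zeros((6, 6))
        for block in (range(3), range(3, 6)):
            for i in block:
                for j in block:
                    if i != j:
                        adj[i, j] = 1
        g = graph_from_adjacency(adj)
        assert characteristic_path_length(g) == 1.0
        report = connectivity_report(g)
        assert not report["connected"]
        assert report["n_unreachable_pairs"] == 18

    def test_edgeless_graph_undefined(self):
        g = graph_from_adjacency(np.zeros((4, 4)), sparsity=0.01)
        with pytest.raises(MetricError):
            characteristic_path_length(g)


class TestEfficiency:
    def test_complete_graph_unit_efficiency(self):
        assert global_efficiency(complete(4)) == 1.0
        assert local_efficiency(complete(4)) == 1.0

    def test_edgeless_graph_zero(self):
        assert global_efficiency(graph_from_adjacency(np.zeros((5, 5)), 0.01)) == 0.0

    def test_random_graph_matches_bfs_oracle(self):
        rng = np.random.default_rng(0)
        adj = random_graph(9, 0.4, rng)
        g = graph_from_adjacency(adj)
        assert abs(global_efficiency(g) - oracle_global_efficiency(adj)) < 1e-12
        assert abs(local_efficiency(g) - oracle_local_efficiency(adj)) < 1e-12


class TestNodalMetrics:
    def test_path_center_betweenness(self):
        sl = nodal_metrics(path_graph(3))
        assert sl.bc[1] == 1.0 and sl.bc[0] == sl.bc[2] == 0.0

    def test_star_center(self):
        sl = nodal_metrics(star(8))
        assert sl.dc[0] == 7
        assert sl.ne[0] == 1.0

    def test_random_graph_matches_enumeration_oracles(self):
        rng = np.random.default_rng(1)
        adj = random_graph(10, 0.35, rng)
        sl = nodal_metrics(graph_from_adjacency(adj))
        assert np.abs(sl.bc - oracle_betweenness(adj)).max() < 1e-10
        assert np.array_equal(sl.dc, adj.sum(axis=0))
        assert np.abs(sl.ne - oracle_nodal_efficiency(adj)).max() < 1e-10
        assert np.abs(sl.nle - oracle_nodal_local_efficiency(adj)).max() < 1e-10

    def test_cycle_graph_betweenness_uniform(self):
        # vertex transitivity: every node lies on the same number of geodesics
        adj = np.zeros((9, 9))
        for i in range(9):
            adj[i, (i + 1) % 9] = adj[(i + 1) % 9, i] = 1
        bc = nodal_metrics(graph_from_adjacency(adj)).bc
        assert np.allclose(bc, bc[0])


class TestNullEnsemble:
    def test_degree_sequence_preserved(self):
        rng = np.random.default_rng(2)
        adj = random_graph(20, 0.25, rng)
        g = graph_from_adjacency(adj)
        from presbynet._rewire import double_edge_swap

        for k in range(5):
            rewired, accepted = double_edge_swap(adj, np.random.default_rng(k))
            assert accepted > 0
            assert np.array_equal(rewired.sum(axis=0), adj.sum(axis=0))
            assert not np.array_equal(rewired, adj)

    def test_lattice_clustering_exceeds_randomized(self):
        g_nx = nx.watts_strogatz_graph(50, 4, 0.0, seed=1)  # pure ring lattice
        g = graph_from_adjacency(nx.to_numpy_array(g_nx))
        ref = random_reference_ensemble(g, n_null=20, seed=3)
        assert ref.cp_rand < clustering_coefficient(g)

    def test_seed_reproducibility(self):
        rng = np.random.default_rng(4)
        g = graph_from_adjacency(random_graph(15, 0.3, rng))
        a = random_reference_ensemble(g, n_null=5, seed=7)
        b = random_reference_ensemble(g, n_null=5, seed=7)
        assert a.cp_rand == b.cp_rand and a.lp_rand == b.lp_rand

    def test_unswappable_star_warns_and_copies(self):
        with pytest.warns(UserWarning, match="rewired"):
            ref = random_reference_ensemble(star(6), n_null=3, seed=0)
        assert ref.cp_rand == clustering_coefficient(star(6))


class TestSmallWorldIndices:
    def test_self_reference_gives_unity(self):
        g = complete(3)  # no valid double-edge swap: nulls are identical copies
        with pytest.warns(UserWarning):
            ref = random_reference_ensemble(g, n_null=3, seed=0)
        gamma, lam, sigma = small_world_indices(g, ref)
        assert gamma == lam == sigma == 1.0

    def test_zero_clustering_null_reference_guarded(self):
        with pytest.warns(UserWarning):
            ref = random_reference_ensemble(star(6), n_null=3, seed=0)
        with pytest.raises(MetricError, match="null reference"):
            small_world_indices(star(6), ref)

    def test_watts_strogatz_is_small_world(self):
        g_nx = nx.watts_strogatz_graph(90, 10, 0.1, seed=5)
        g = graph_from_adjacency(nx.to_numpy_array(g_nx))
        ref = random_reference_ensemble(g, n_null=20, seed=6)
        gamma, lam, sigma = small_world_indices(g, ref)
        assert gamma > 1.0 and sigma > 1.0

    def test_random_graph_gamma_near_unity(self):
        # degree-preserving randomization of an already random graph
        gammas = []
        for rep in range(20):
            adj = random_graph(200, 0.05, np.random.default_rng(100 + rep))
            g = graph_from_adjacency(adj)
            ref = random_reference_ensemble(g, n_null=5, seed=rep)
            gammas.append(clustering_coefficient(g) / ref.cp_rand)
        assert abs(np.mean(gammas) - 1.0) < 0.2


class TestAUC:
    def test_constant_curve(self):
        grid = sparsity_grid()
        assert abs(metric_auc(np.full(35, 2.0), grid) - 0.68) < 1e-12

    def test_linear_ramp(self):
        assert abs(metric_auc([0.0, 0.5, 1.0], [0.0, 0.5, 1.0]) - 0.5) < 1e-12

    def test_matches_direct_summation_oracle(self):
        rng = np.random.default_rng(5)
        grid = sparsity_grid()
        vals = rng.normal(size=35)
        assert abs(metric_auc(vals, grid) - oracle_trapezoid(vals, grid)) < 1e-12

    def test_linearity(self):
        rng = np.random.default_rng(6)
        grid = sparsity_grid()
        x, y = rng.normal(size=(2, 35))
        lhs = metric_auc(3.0 * x + 2.0 * y, grid)
        rhs = 3.0 * metric_auc(x, grid) + 2.0 * metric_auc(y, grid)
        assert abs(lhs - rhs) < 1e-10

    def test_length_mismatch(self):
        with pytest.raises(MetricError):
            metric_auc([1.0, 2.0], sparsity_grid())


class TestGridProfiles:
    def test_series_of_complete_graphs(self):
        n = 12
        conn = ConnectivityMatrix(np.ones((n, n)) - np.eye(n), [f"r{i}" for i in range(n)])
        series = build_threshold_series(conn, [0.9, 1.0])
        # at full sparsity the graph is complete: Cp = Eglob = 1
        assert clustering_coefficient(series.graphs[-1]) == 1.0
        assert global_efficiency(series.graphs[-1]) == 1.0

    def test_nested_series_monotonicity(self):
        rng = np.random.default_rng(7)
        w = rng.normal(size=(30, 30))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0)
        conn = ConnectivityMatrix(w, [f"r{i}" for i in range(30)])
        series = build_threshold_series(conn, sparsity_grid(0.1, 0.5, 0.1))
        eglob = [global_efficiency(g) for g in series.graphs]
        lp = [characteristic_path_length(g) for g in series.graphs]
        assert (np.diff(eglob) >= -1e-12).all()
        assert (np.diff(lp) <= 1e-12).all()

    def test_profile_shape_and_reports(self):
        rng = np.random.default_rng(8)
        w = rng.normal(size=(25, 25))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0)
        conn = ConnectivityMatrix(w, [f"r{i}" for i in range(25)])
        series = build_threshold_series(conn, sparsity_grid(0.1, 0.4, 0.1))
        profile = global_metrics_over_grid(series, n_null=3, seed=1)
        assert profile.curves.shape == (4, 7)
        assert set(profile.auc) == {"Cp", "Lp", "Eglob", "Eloc", "gamma", "lambda", "sigma"}
        assert profile.monotonicity["Eglob_nondecreasing"]
        assert profile.monotonicity["Lp_nonincreasing"]
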