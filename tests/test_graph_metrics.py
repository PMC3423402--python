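import numpy as np
import pytest

import _oracles as oracle
from connmod import graph_metrics as gm
from connmod.connectivity import ConnectivityMatrix
from connmod.exceptions import DisconnectedGraphError, InvalidArgumentError


def _graph(weights):
    w = np.asarray(weights, float)
    return gm.SparseGraph(w, density=1.0)


def _pen(weights):
    w = np.asarray(weights, float)
    np.fill_diagonal(w, 0.0)
    return ConnectivityMatrix(w, "penalized")


class TestThresholdGraph:
    def test_full_density_keeps_positive_matrix(self):
        rng = np.random.default_rng(0)
        w = oracle.random_connected_weighted_graph(8, 0.9, rng)
        g = gm.threshold_graph(_pen(w.copy()), 1.0)
        np.testing.assert_allclose(g.weights, w)

    def test_matches_greedy_reference_on_random_matrices(self):
        rng = np.random.default_rng(1)
        for _ in range(15):
            n = int(rng.integers(6, 11))
            w = oracle.random_connected_weighted_graph(n, 0.8, rng, signed=True)
            density = float(rng.uniform(0.3, 0.8))
            ours = gm.threshold_graph(_pen(w.copy()), density).weights
            ref = oracle.greedy_threshold_reference(w, density)
            np.testing.assert_allclose(ours, ref)

    def test_k4_half_density_brute_force(self):
        # complete graph on 4 nodes with distinct weights, 50% density -> 3 edges
        w = np.zeros((4, 4))
        vals = {(0, 1): 0.9, (0, 2): 0.8, (0, 3): 0.1, (1, 2): 0.7, (1, 3): 0.2, (2, 3): 0.3}
        for (i, j), v in vals.items():
            w[i, j] = w[j, i] = v
        g = gm.threshold_graph(_pen(w.copy()), 0.5)
        assert g.n_edges == 3
        np.testing.assert_allclose(g.weights, oracle.greedy_threshold_reference(w, 0.5))

    def test_atlas_scale_edge_count(self):
        rng = np.random.default_rng(2)
        w = rng.normal(0.05, 0.2, (95, 95))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0.0)
        g = gm.threshold_graph(_pen(w), 0.12)
        assert gm.edge_target(95, 0.12) == 536
        assert abs(g.n_edges - 536) <= 1
        import networkx as nx

        assert nx.is_connected(g.to_networkx())

    def test_unreachable_density_flags_minimal_graph(self):
        # a path graph cannot go below N-1 edges without disconnecting
        w = np.zeros((6, 6))
        for i in range(5):
            w[i, i + 1] = w[i + 1, i] = 0.5 + 0.05 * i
        g = gm.threshold_graph(_pen(w), 0.1)  # target round(0.1*15)=2 < 5
        assert g.target_missed
        assert g.n_edges == 5

    def test_disconnected_positive_part_rejected(self):
        w = np.zeros((4, 4))
        w[0, 1] = w[1, 0] = 0.5
        w[2, 3] = w[3, 2] = 0.5
        with pytest.raises(DisconnectedGraphError):
            gm.threshold_graph(_pen(w), 0.5)


class TestMetricsAgainstBruteForce:
    def test_unit_triangle_and_path(self):
        tri = np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], float)
        assert gm.path_length(_graph(tri)) == pytest.approx(1.0)
        assert gm.global_efficiency(_graph(tri)) == pytest.approx(1.0)
        path = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], float)
        assert gm.path_length(_graph(path)) == pytest.approx(4 / 3)
        assert gm.global_efficiency(_graph(path)) == pytest.approx(5 / 6)

    def test_random_graphs_match_enumeration(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            n = int(rng.integers(5, 11))
            w = oracle.random_connected_weighted_graph(n, 0.7, rng)
            g = _graph(w)
            assert gm.path_length(g) == pytest.approx(
                oracle.brute_path_length(w), abs=1e-9
            )
            assert gm.global_efficiency(g) == pytest.approx(
                oracle.brute_global_efficiency(w), abs=1e-9
            )
            np.testing.assert_allclose(
                gm.clustering_coefficient(g, nodal=True),
                oracle.brute_onnela_clustering(w),
                atol=1e-9,
            )

    def test_clustering_extremes(self):
        k5 = np.ones((5, 5)) - np.eye(5)
        assert gm.clustering_coefficient(_graph(k5)) == pytest.approx(1.0)
        star = np.zeros((5, 5))
        star[0, 1:] = star[1:, 0] = 1.0
        assert gm.clustering_coefficient(_graph(star)) == pytest.approx(0.0)

    def test_betweenness_closed_forms(self):
        path = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], float)
        np.testing.assert_allclose(gm.betweenness(_graph(path)), [0, 1, 0])
        star = np.zeros((5, 5))
        star[0, 1:] = star[1:, 0] = 1.0
        bc = gm.betweenness(_graph(star))
        assert bc[0] == pytest.approx(6.0)  # C(4,2) pairs through the hub
        np.testing.assert_allclose(bc[1:], 0.0)

    def test_betweenness_matches_path_enumeration(self):
        rng = np.random.default_rng(4)
        for _ in range(5):
            w = oracle.random_connected_weighted_graph(7, 0.6, rng)
            np.testing.assert_allclose(
                gm.betweenness(_graph(w)), oracle.brute_betweenness(w), atol=1e-9
            )

    def test_path_length_requires_connected(self):
        w = np.zeros((4, 4))
        w[0, 1] = w[1, 0] = 1.0
        w[2, 3] = w[3, 2] = 1.0
        with pytest.raises(DisconnectedGraphError):
            gm.path_length(_graph(w))


def _ring_lattice(n=20, k=2):
    w = np.zeros((n, n))
    for i in range(n):
        for d in range(1, k + 1):
            j = (i + d) % n
            w[i, j] = w[j, i] = 1.0
    return w


class TestRandomReference:
    def test_degree_and_weight_multiset_preserved(self):
        rng = np.random.default_rng(5)
        w = oracle.random_connected_weighted_graph(12, 0.4, rng)
        g = _graph(w)
        r = gm.random_reference(g, seed=0, n_swaps_per_edge=5)
        np.testing.assert_array_equal(
            (r.weights > 0).sum(1), (w > 0).sum(1)
        )
        iu = np.triu_indices(12, 1)
        np.testing.assert_allclose(
            np.sort(r.weights[iu][r.weights[iu] > 0]),
            np.sort(w[iu][w[iu] > 0]),
        )
        import networkx as nx

        assert nx.is_connected(r.to_networkx())

    def test_randomization_destroys_clustering(self):
        g = _graph(_ring_lattice())
        cc0 = gm.clustering_coefficient(g)
        refs = [gm.random_reference(g, seed=s) for s in range(10)]
        assert np.mean([gm.clustering_coefficient(r) for r in refs]) < cc0


class TestSmallWorldIndex:
    def test_self_reference_is_unity(self):
        rng = np.random.default_rng(6)
        w = oracle.random_connected_weighted_graph(10, 0.5, rng)
        g = _graph(w)
        swi, ccn, pln = gm.small_world_index(g, [g, g])
        assert swi == pytest.approx(1.0)
        assert ccn == pytest.approx(1.0)
        assert pln == pytest.approx(1.0)

    def test_lattice_is_small_world_against_random(self):
        g = _graph(_ring_lattice())
        refs = [gm.random_reference(g, seed=s, n_swaps_per_edge=10) for s in range(10)]
        swi, ccn, pln = gm.small_world_index(g, refs)
        assert ccn / pln == pytest.approx(swi)
        assert swi > 1.0


class TestCurves:
    def test_grid_has_26_points(self, small_penalized):
        assert len(gm.DEFAULT_THRESHOLDS) == 26

    def test_single_threshold_equals_direct_call(self, small_penalized):
        pen, _ = small_penalized
        curve = gm.metric_threshold_curve(pen[0], thresholds=(0.3,), n_refs=2, seed=5)
        direct = gm.global_metrics_at(pen[0], 0.3, n_refs=2, seed=5)
        assert curve[0] == direct

    def test_density_monotone_in_edge_count(self, small_penalized):
        pen, _ = small_penalized
        counts = [
            gm.threshold_graph(pen[0], d).n_edges for d in (0.15, 0.25, 0.35, 0.5)
        ]
        assert counts == sorted(counts) and len(set(counts)) == len(counts)

    def test_auc_constant_linear_and_midpoint(self):
        t = np.linspace(0.10, 0.35, 26)
        assert gm.curve_auc(t, np.full(26, 2.0)) == pytest.approx(0.5)
        assert gm.curve_auc(t, 4 * t) == pytest.approx(2 * (0.35**2 - 0.10**2))
        rng = np.random.default_rng(7)
        y = rng.random(26)
        mid = float(np.sum((y[1:] + y[:-1]) / 2 * np.diff(t)))
        assert gm.curve_auc(t, y) == pytest.approx(mid)
        # unsorted input is sorted internally
        perm = rng.permutation(26)
        assert gm.curve_auc(t[perm], y[perm]) == pytest.approx(gm.curve_auc(t, y))


def test_node_metric_table_contract(small_penalized, small_cohort):
    pen, _ = small_penalized
    g = gm.threshold_graph(pen[0], 0.3)
    tab = gm.node_metric_table(g, small_cohort.parcellation.region_names)
    assert list(tab.columns) == ["degree", "strength", "BC", "CC", "LE", "GE", "LEGE"]
    assert len(tab) == 20
    assert (tab["degree"] >= 1).all()
    assert (tab["BC"] >= 0).all()
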