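import numpy as np
import pytest

from oracles import (
    brute_betweenness,
    brute_clustering,
    brute_local_efficiency,
    brute_shortest_paths,
    random_weighted_graph,
)

from connectoprofile.errors import MetricUndefinedError
from connectoprofile.io import ConnectivityMatrix, NodeTable
from connectoprofile.metrics import (
    NullModelConfig,
    all_pairs_shortest_paths,
    betweenness_centrality,
    characteristic_path_length,
    clustering_coefficients,
    compute_metric_profile,
    global_efficiency,
    local_efficiency,
    navigation_efficiency,
    node_strengths,
    normalized_clustering,
    remap_weights_to_lengths,
    rewired_surrogate,
)


def complete_graph(n, weight=1.0):
    w = np.full((n, n), weight)
    np.fill_diagonal(w, 0.0)
    return w


class TestRemapAndShortestPaths:
    @pytest.mark.parametrize("w,expected", [(1.0, 1.0), (4.0, 0.25)])
    def test_reciprocal_remap(self, w, expected):
        lengths = remap_weights_to_lengths(np.array([[0, w], [w, 0.0]]))
        assert lengths[0, 1] == expected

    def test_zero_weight_is_no_edge(self):
        lengths = remap_weights_to_lengths(np.array([[0, 0.0], [0, 0]]))
        assert np.isinf(lengths[0, 1])

    def test_path_graph_distances(self, path3):
        d = all_pairs_shortest_paths(remap_weights_to_lengths(path3.weights))
        np.testing.assert_allclose(d, [[0, 1, 2], [1, 0, 1], [2, 1, 0]])

    def test_two_hop_beats_weak_direct_edge(self):
        # direct A-B weight 1 (length 1) vs A-C-B via two weight-10 edges (0.2)
        w = np.array([[0, 1, 10], [1, 0, 10], [10, 10, 0.0]])
        d = all_pairs_shortest_paths(remap_weights_to_lengths(w))
        assert d[0, 1] == pytest.approx(0.2)

    def test_disconnected_dyads_infinite(self):
        w = np.zeros((4, 4))
        w[0, 1] = w[1, 0] = 1
        w[2, 3] = w[3, 2] = 1
        d = all_pairs_shortest_paths(remap_weights_to_lengths(w))
        assert np.isinf(d[0, 2]) and np.isinf(d[1, 3])


class TestAggregateMetrics:
    def test_path_graph_char_path_length(self, path3):
        d = all_pairs_shortest_paths(remap_weights_to_lengths(path3.weights))
        L, excluded = characteristic_path_length(d)
        assert L == pytest.approx(4 / 3) and excluded == 0

    def test_complete_graph_L_is_1(self):
        d = all_pairs_shortest_paths(remap_weights_to_lengths(complete_graph(4)))
        assert characteristic_path_length(d)[0] == pytest.approx(1.0)

    def test_isolated_node_excluded_from_L(self):
        w = complete_graph(4)
        w[3, :] = w[:, 3] = 0
        L, excluded = characteristic_path_length(d := all_pairs_shortest_paths(
            remap_weights_to_lengths(w)))
        assert L == pytest.approx(1.0) and excluded == 3

    def test_fully_disconnected_L_undefined(self):
        with pytest.raises(MetricUndefinedError):
            characteristic_path_length(all_pairs_shortest_paths(
                remap_weights_to_lengths(np.zeros((3, 3)))))

    def test_path_graph_global_efficiency(self, path3):
        d = all_pairs_shortest_paths(remap_weights_to_lengths(path3.weights))
        assert global_efficiency(d) == pytest.approx(5 / 6)

    def test_disconnected_graph_efficiency_zero(self):
        d = all_pairs_shortest_paths(remap_weights_to_lengths(np.zeros((3, 3))))
        assert global_efficiency(d) == 0.0

    def test_triangle_strengths(self, triangle):
        s = node_strengths(triangle.weights)
        np.testing.assert_allclose(s, [4, 3, 5])
        assert s.mean() == pytest.approx(4)

    def test_strength_linearity(self, triangle):
        np.testing.assert_allclose(
            node_strengths(2 * triangle.weights), 2 * node_strengths(triangle.weights)
        )


class TestClustering:
    def test_equal_triangle_is_1(self):
        c = clustering_coefficients(complete_graph(3, 2.5))
        np.testing.assert_allclose(c, 1.0)

    def test_path_graph_no_triangles(self, path3):
        np.testing.assert_allclose(clustering_coefficients(path3.weights), 0.0)

    def test_unequal_triangle_hand_value(self):
        # weights 1,1,8 -> normalized (0.125, 0.125, 1); each C_i = 0.25
        w = np.array([[0, 1, 8], [1, 0, 1], [8, 1, 0.0]])
        np.testing.assert_allclose(clustering_coefficients(w), 0.25)


class TestLocalEfficiency:
    def test_triangle_all_ones(self):
        np.testing.assert_allclose(local_efficiency(complete_graph(3, 3.0)), 1.0)

    def test_star_graph_zero(self):
        w = np.zeros((4, 4))
        w[0, 1:] = w[1:, 0] = 1.0
        np.testing.assert_allclose(local_efficiency(w), 0.0)

    def test_k4_all_ones(self):
        np.testing.assert_allclose(local_efficiency(complete_graph(4)), 1.0)


class TestBetweenness:
    def test_path_graph(self, path3):
        bc = betweenness_centrality(remap_weights_to_lengths(path3.weights))
        np.testing.assert_allclose(bc, [0, 1, 0])

    def test_complete_graph_zero(self):
        bc = betweenness_centrality(remap_weights_to_lengths(complete_graph(5)))
        np.testing.assert_allclose(bc, 0.0)

    def test_four_cycle_fractional_ties(self):
        w = np.zeros((4, 4))
        for i, j in [(0, 1), (1, 2), (2, 3), (3, 0)]:
            w[i, j] = w[j, i] = 1.0
        bc = betweenness_centrality(remap_weights_to_lengths(w))
        np.testing.assert_allclose(bc, 0.5)


class TestOracleEquivalence:
    """Exact agreement with brute-force enumeration on small random graphs."""

    @pytest.mark.parametrize("seed", range(30))
    def test_shortest_paths_and_betweenness(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 8))
        w = random_weighted_graph(rng, n, density=0.6)
        lengths = remap_weights_to_lengths(w)
        np.testing.assert_allclose(
            all_pairs_shortest_paths(lengths), brute_shortest_paths(lengths), rtol=1e-12
        )
        np.testing.assert_allclose(
            betweenness_centrality(lengths), brute_betweenness(lengths), atol=1e-9
        )

    @pytest.mark.parametrize("seed", range(30))
    def test_clustering_and_local_efficiency(self, seed):
        rng = np.random.default_rng(seed + 1000)
        n = int(rng.integers(4, 9))
        w = random_weighted_graph(rng, n, density=0.6)
        np.testing.assert_allclose(
            clustering_coefficients(w), brute_clustering(w), rtol=1e-10, atol=1e-12
        )
        np.testing.assert_allclose(
            local_efficiency(w), brute_local_efficiency(w), rtol=1e-10, atol=1e-12
        )


class TestNavigation:
    def test_collinear_path(self, path3, collinear_nodes):
        e_nav, success = navigation_efficiency(path3.weights, collinear_nodes.coords)
        assert success.sum() == 6
        assert e_nav == pytest.approx(5 / 6)

    def test_complete_graph_single_hops(self):
        rng = np.random.default_rng(3)
        coords = rng.normal(size=(5, 3)) * 20
        w = complete_graph(5, 2.0)
        e_nav, success = navigation_efficiency(w, coords)
        off_diag = ~np.eye(5, dtype=bool)
        assert success[off_diag].all()
        assert e_nav == pytest.approx(2.0)  # every walk is the direct length-1/2 edge

    def test_dead_end_pair_fails(self):
        # from s the geometrically closest neighbour u is a dead end whose
        # only way out revisits s, so the walk s -> t fails and scores 0
        coords = np.array([[0.0, 0, 0],   # s
                           [1.0, 0, 0],   # u (dead end, closest to t)
                           [3.0, 0, 0],   # t
                           [0.0, 5, 0]])  # v (detour that actually reaches t)
        w = np.zeros((4, 4))
        for i, j in [(0, 1), (0, 3), (3, 2)]:
            w[i, j] = w[j, i] = 1.0
        e_nav, success = navigation_efficiency(w, coords)
        assert not success[0, 2]
        assert success[2, 0]  # the reverse direction routes through v fine

    @pytest.mark.parametrize("seed", range(20))
    def test_navigation_never_beats_shortest_path(self, seed):
        rng = np.random.default_rng(seed)
        n = 8
        w = random_weighted_graph(rng, n, density=0.7)
        coords = rng.normal(size=(n, 3)) * 30
        lengths = remap_weights_to_lengths(w)
        d = all_pairs_shortest_paths(lengths)
        e_nav, success = navigation_efficiency(w, coords)
        e_glob_pairs = global_efficiency(d)
        # mean pairwise navigation efficiency cannot exceed mean shortest-path efficiency
        assert e_nav <= e_glob_pairs + 1e-12


class TestNullModel:
    def test_complete_graph_cnorm_1(self):
        w = complete_graph(6, 2.0)
        assert normalized_clustering(w, NullModelConfig(n_nulls=5, seed=1)) == pytest.approx(1.0)

    def test_surrogate_preserves_degrees_and_weights(self):
        rng = np.random.default_rng(11)
        w = random_weighted_graph(rng, 12, density=0.4)
        surr = rewired_surrogate(w, np.random.default_rng(5), rewires_per_edge=10)
        assert np.array_equal(surr > 0, surr.T > 0)
        np.testing.assert_array_equal((surr > 0).sum(axis=1), (w > 0).sum(axis=1))
        iu = np.triu_indices(12, k=1)
        np.testing.assert_allclose(
            np.sort(surr[iu][surr[iu] > 0]), np.sort(w[iu][w[iu] > 0])
        )

    def test_ring_lattice_cnorm_above_1(self):
        # ring lattice with k=4 neighbours: strongly clustered vs rewired nulls
        n = 30
        w = np.zeros((n, n))
        for i in range(n):
            for off in (1, 2):
                j = (i + off) % n
                w[i, j] = w[j, i] = 1.0
        cnorm = normalized_clustering(w, NullModelConfig(n_nulls=20, seed=2))
        assert cnorm > 1.5

    def test_random_graph_cnorm_near_1(self):
        rng = np.random.default_rng(8)
        w = random_weighted_graph(rng, 40, density=0.3)
        cnorm = normalized_clustering(w, NullModelConfig(n_nulls=30, seed=3))
        assert cnorm == pytest.approx(1.0, abs=0.15)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(21)
        w = random_weighted_graph(rng, 15, density=0.5)
        cfg = NullModelConfig(n_nulls=10, seed=99)
        assert normalized_clustering(w, cfg) == normalized_clustering(w, cfg)


class TestProfileAndScaling:
    def test_complete_k5_closed_forms(self):
        nodes = NodeTable(
            labels=[f"n{i}" for i in range(5)],
            hemispheres=["midline"] * 5,
            coords=np.random.default_rng(0).normal(size=(5, 3)),
        )
        m = ConnectivityMatrix(weights=complete_graph(5), subject_id="k5")
        prof = compute_metric_profile(m, nodes, NullModelConfig(n_nulls=3, seed=0))
        assert prof.strength == pytest.approx(4)
        assert prof.char_path_length == pytest.approx(1)
        assert prof.global_efficiency == pytest.approx(1)
        assert prof.betweenness == pytest.approx(0)
        assert prof.clustering == pytest.approx(1)
        assert prof.local_efficiency == pytest.approx(1)

    def test_uniform_scaling_behaviour(self):
        rng = np.random.default_rng(17)
        n = 10
        w = random_weighted_graph(rng, n, density=0.7)
        coords = rng.normal(size=(n, 3)) * 25
        nodes = NodeTable(labels=[f"n{i}" for i in range(n)],
                          hemispheres=["midline"] * n, coords=coords)
        cfg = NullModelConfig(n_nulls=5, seed=4)
        c = 3.7
        p1 = compute_metric_profile(ConnectivityMatrix(weights=w, subject_id="a"), nodes, cfg)
        p2 = compute_metric_profile(ConnectivityMatrix(weights=c * w, subject_id="b"), nodes, cfg)
        assert p2.strength == pytest.approx(c * p1.strength)
        assert p2.char_path_length == pytest.approx(p1.char_path_length / c)
        assert p2.global_efficiency == pytest.approx(c * p1.global_efficiency)
        assert p2.navigation_efficiency == pytest.approx(c * p1.navigation_efficiency)
        assert p2.clustering == pytest.approx(p1.clustering)
        assert p2.normalized_clustering == pytest.approx(p1.normalized_clustering)
        assert p2.betweenness == pytest.approx(p1.betweenness)

    def test_profile_determinism(self, tiny_study):
        nodes = tiny_study["nodes"]
        m = tiny_study["controls"][0]
        cfg = NullModelConfig(n_nulls=10, seed=123)
        a = compute_metric_profile(m, nodes, cfg)
        b = compute_metric_profile(m, nodes, cfg)
        assert a.values() == b.values()
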