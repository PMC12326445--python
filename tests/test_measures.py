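"""Comparison graph measures against hand values and independent oracles."""

import numpy as np
import pytest

import oracles
from rsvnet import (
    WeightedNetwork,
    all_measures,
    assortativity,
    clustering_norm,
    diffusion_efficiency,
    mean_edge_weight,
    mean_first_passage_times,
    routing_efficiency,
    strength_variance,
)
from rsvnet.measures import DisconnectedNetworkError, MeasureComputationError
from rsvnet.replicate import monte_carlo_mfpt
from conftest import random_connected_network


class TestStrengthVariance:
    def test_star_strengths_variance_one(self, star4):
        # strengths (3,1,1,1): sample variance 1
        assert strength_variance(star4) == pytest.approx(1.0)

    def test_regular_graph_zero(self, k4):
        assert strength_variance(k4) == 0.0

    def test_scaling_law(self, weighted_triangle):
        base = strength_variance(weighted_triangle)
        scaled = weighted_triangle.with_weights(weighted_triangle.weights * 3.0)
        assert strength_variance(scaled) == pytest.approx(9.0 * base)


class TestAssortativity:
    def test_matches_endpoint_pearson_oracle(self):
        rng = np.random.default_rng(13)
        for _ in range(25):
            net = random_connected_network(rng)
            want = oracles.endpoint_pearson_assortativity(net.weights.tolist())
            assert assortativity(net) == pytest.approx(want, abs=1e-10)

    def test_two_cliques_positive(self):
        # disjoint uniform cliques of different sizes: like connects to like
        W = np.zeros((7, 7))
        W[:3, :3] = 1.0
        W[3:, 3:] = 1.0
        np.fill_diagonal(W, 0.0)
        net = WeightedNetwork.from_matrix(W)
        assert assortativity(net) > 0

    def test_star_negative(self, star4):
        assert assortativity(star4) < 0

    def test_regular_graph_undefined_not_zero(self, k4):
        with pytest.warns(RuntimeWarning, match="undefined"):
            assert np.isnan(assortativity(k4))


class TestClustering:
    def test_unit_triangle_gamma_one(self):
        W = np.ones((3, 3)) - np.eye(3)
        assert clustering_norm(WeightedNetwork.from_matrix(W)) == pytest.approx(1.0)

    def test_path_has_no_triangles(self):
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = W[1, 2] = W[2, 1] = 1.0
        assert clustering_norm(WeightedNetwork.from_matrix(W)) == 0.0

    def test_matches_triple_product_oracle(self, weighted_triangle):
        from rsvnet.measures import onnela_clustering
        want = oracles.onnela_mean_clustering(weighted_triangle.weights.tolist())
        assert onnela_clustering(weighted_triangle) == pytest.approx(want, abs=1e-12)

    def test_random_graphs_match_oracle(self):
        rng = np.random.default_rng(29)
        from rsvnet.measures import onnela_clustering
        for _ in range(20):
            net = random_connected_network(rng)
            want = oracles.onnela_mean_clustering(net.weights.tolist())
            assert onnela_clustering(net) == pytest.approx(want, abs=1e-12)


class TestRoutingEfficiency:
    def test_complete_unit_graph_is_one(self, k4):
        assert routing_efficiency(k4) == pytest.approx(1.0)

    def test_doubling_weights_doubles_efficiency(self, weighted_triangle):
        base = routing_efficiency(weighted_triangle)
        doubled = weighted_triangle.with_weights(weighted_triangle.weights * 2)
        assert routing_efficiency(doubled) == pytest.approx(2 * base, rel=1e-12)

    def test_matches_floyd_warshall_oracle(self):
        rng = np.random.default_rng(31)
        for _ in range(25):
            net = random_connected_network(rng, n_min=6, n_max=9)
            want = oracles.floyd_warshall_efficiency(net.weights.tolist())
            assert routing_efficiency(net) == pytest.approx(want, abs=1e-12)

    def test_disconnected_pairs_contribute_zero(self):
        W = np.zeros((4, 4))
        W[0, 1] = W[1, 0] = 1.0
        W[2, 3] = W[3, 2] = 1.0
        net = WeightedNetwork.from_matrix(W)
        # 4 reachable ordered pairs with d=1, out of 12
        assert routing_efficiency(net) == pytest.approx(4 / 12)


class TestDiffusionEfficiency:
    def test_two_node_single_step(self):
        W = np.array([[0.0, 2.5], [2.5, 0.0]])
        net = WeightedNetwork.from_matrix(W)
        T = mean_first_passage_times(net)
        assert T[0, 1] == pytest.approx(1.0)
        assert diffusion_efficiency(net) == pytest.approx(1.0)

    def test_unit_triangle(self):
        W = np.ones((3, 3)) - np.eye(3)
        net = WeightedNetwork.from_matrix(W)
        # from any node, t solves t = 1/2 * 1 + 1/2 * (1 + t) -> t = 2
        T = mean_first_passage_times(net)
        assert np.allclose(T[~np.eye(3, dtype=bool)], 2.0)
        assert diffusion_efficiency(net) == pytest.approx(0.5)

    def test_closed_form_within_monte_carlo_band(self):
        rng = np.random.default_rng(41)
        net = random_connected_network(rng, n_min=5, n_max=7)
        T = mean_first_passage_times(net)
        for (i, j) in [(0, 1), (1, 3), (net.n_nodes - 1, 0)]:
            est, se = monte_carlo_mfpt(net, i, j, n_walkers=20_000, seed=7)
            assert abs(est - T[i, j]) <= 3 * se

    def test_disconnected_network_refused(self):
        W = np.zeros((4, 4))
        W[0, 1] = W[1, 0] = 1.0
        W[2, 3] = W[3, 2] = 1.0
        with pytest.raises(DisconnectedNetworkError, match="component"):
            diffusion_efficiency(WeightedNetwork.from_matrix(W))


class TestAllMeasures:
    def test_k4_composite(self, k4):
        with pytest.warns(RuntimeWarning):
            ms = all_measures(k4)
        assert ms.strength_variance == 0.0
        assert ms.clustering_norm == pytest.approx(1.0)
        assert ms.routing_efficiency == pytest.approx(1.0)
        assert ms.diffusion_efficiency > 0
        assert np.isnan(ms.assortativity)

    def test_edgeless_graph_structured_error(self):
        net = WeightedNetwork.from_matrix(np.zeros((4, 4)))
        with pytest.raises(MeasureComputationError) as err:
            all_measures(net)
        assert "clustering_norm" in err.value.errors

    def test_non_strict_mode_reports_nan(self):
        net = WeightedNetwork.from_matrix(np.zeros((4, 4)))
        ms = all_measures(net, strict=False)
        assert np.isnan(ms.clustering_norm)
        assert "errors" in ms.params

    def test_deterministic(self, weighted_triangle):
        a = all_measures(weighted_triangle)
        b = all_measures(weighted_triangle)
        assert a.diffusion_efficiency == b.diffusion_efficiency
        assert a.routing_efficiency == b.routing_efficiency

    def test_mean_edge_weight(self, weighted_triangle):
        assert mean_edge_weight(weighted_triangle) == pytest.approx(2.0)
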