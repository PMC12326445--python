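"""Relative strength, RSV, sliding-window hRSV and tier decompositions."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import oracles
from rsvnet import (
    WeightedNetwork,
    assign_tiers,
    hrsv,
    node_strengths,
    relative_strengths,
    rsv,
    tier_hrsv,
)
from rsvnet.rsv import DegenerateTermError, IsolatedNodeError
from conftest import random_connected_network


class TestNodeStrengths:
    def test_star_strengths(self, star4):
        np.testing.assert_allclose(node_strengths(star4), [3, 1, 1, 1])

    def test_weighted_triangle_strengths(self, weighted_triangle):
        np.testing.assert_allclose(node_strengths(weighted_triangle), [4, 3, 5])

    def test_empty_network_zero_strengths(self):
        net = WeightedNetwork.from_matrix(np.zeros((3, 3)))
        np.testing.assert_array_equal(node_strengths(net), np.zeros(3))


class TestRelativeStrengths:
    @pytest.mark.parametrize("corrected", [False, True])
    def test_complete_graph_all_ones(self, k4, corrected):
        prof = relative_strengths(k4, corrected=corrected)
        np.testing.assert_allclose(prof.r, np.ones(4), atol=1e-14)

    def test_star_uncorrected_hub_and_leaves(self, star4):
        prof = relative_strengths(star4, corrected=False)
        np.testing.assert_allclose(prof.r, [3, 1 / 3, 1 / 3, 1 / 3])

    def test_star_corrected_is_fully_degenerate(self, star4):
        # every leaf's only edge is the hub edge: s_leaf - W = 0
        with pytest.raises(DegenerateTermError):
            relative_strengths(star4, corrected=True, degenerate="strict")
        with pytest.raises(DegenerateTermError):
            # skip policy also fails: all of a leaf's terms are degenerate
            relative_strengths(star4, corrected=True, degenerate="skip")

    def test_leaf_neighbour_contributes_zero_term(self):
        # C's term via leaf D has numerator s_D - W_CD = 0: the term is 0,
        # deflating the mean ratio and inflating r_C, exactly as the
        # edge-corrected definition dictates
        W = np.array([
            [0, 1, 1, 0],
            [1, 0, 1, 0],
            [1, 1, 0, 2],
            [0, 0, 2, 0],
        ], dtype=float)
        net = WeightedNetwork.from_matrix(W)
        with pytest.raises(DegenerateTermError):
            # leaf D itself has no valid term, so the profile is undefined
            relative_strengths(net, corrected=True, degenerate="skip")

    def test_isolated_node_named_in_error(self):
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = 1.0
        net = WeightedNetwork.from_matrix(W, node_labels=("A", "B", "LONER"))
        with pytest.raises(IsolatedNodeError, match="LONER"):
            relative_strengths(net, corrected=False)

    @pytest.mark.parametrize("corrected", [False, True])
    def test_matches_straight_line_oracle(self, corrected):
        rng = np.random.default_rng(11)
        for _ in range(50):
            net = random_connected_network(rng)
            prof = relative_strengths(net, corrected=corrected)
            expected = oracles.relative_strengths(net.weights.tolist(), corrected)
            np.testing.assert_allclose(prof.r, expected, atol=1e-12)


class TestRSV:
    def test_complete_graph_zero(self, k4):
        assert rsv(k4).value == 0.0

    def test_star_uncorrected_four_thirds(self, star4):
        result = rsv(star4, corrected=False)
        assert result.value == pytest.approx(4 / 3, abs=1e-14)
        assert result.variance == pytest.approx((4 / 3) ** 2, abs=1e-12)
        assert result.mu_r == pytest.approx((3 + 1) / 4)

    def test_single_window_limit_equals_rsv_exactly(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            net = random_connected_network(rng)
            assert hrsv(net, net.n_nodes).value == rsv(net).value

    def test_too_few_nodes_rejected(self):
        net = WeightedNetwork.from_matrix(np.array([[0.0]]))
        with pytest.raises(ValueError):
            rsv(net)

    @given(st.integers(min_value=0, max_value=2**31 - 1),
           st.floats(min_value=0.01, max_value=100.0))
    @settings(max_examples=30, deadline=None)
    def test_scale_invariance(self, seed, c):
        # continuous weights: distinct strengths, so the rank order the
        # windows rely on cannot flip under rescaling (exact integer
        # strength ties can re-sort once multiplied by an inexact float)
        rng = np.random.default_rng(seed)
        net = random_connected_network(rng)
        jitter = rng.random(net.weights.shape)
        jitter = np.triu(jitter, 1) + np.triu(jitter, 1).T
        net = net.with_weights(net.weights * (1.0 + 0.1 * jitter))
        scaled = net.with_weights(net.weights * c)
        base = rsv(net).value
        assert rsv(scaled).value == pytest.approx(base, rel=1e-12, abs=1e-12)
        w = min(3, net.n_nodes)
        assert hrsv(scaled, w).value == pytest.approx(hrsv(net, w).value,
                                                      rel=1e-12, abs=1e-12)


class TestHRSV:
    def test_window_count_is_n_minus_w_plus_1(self):
        rng = np.random.default_rng(3)
        net = random_connected_network(rng, n_min=6, n_max=7)
        res = hrsv(net, 4)
        assert len(res.per_window) == net.n_nodes - 4 + 1
        assert res.value == pytest.approx(res.per_window.mean())

    def test_equal_relative_strengths_give_zero(self, k4):
        for w in (2, 3, 4):
            assert hrsv(k4, w).value == pytest.approx(0.0, abs=1e-14)

    @pytest.mark.parametrize("corrected", [False, True])
    def test_matches_brute_force_oracle(self, corrected):
        rng = np.random.default_rng(21)
        for _ in range(50):
            net = random_connected_network(rng, n_min=5, n_max=7)
            for w in (2, 3, 4):
                got = hrsv(net, w, corrected=corrected).value
                want = oracles.hrsv(net.weights.tolist(), w, corrected)
                assert got == pytest.approx(want, abs=1e-12)

    def test_population_ordering_changes_windows(self):
        rng = np.random.default_rng(9)
        net = random_connected_network(rng, n_min=6, n_max=7)
        pop = rng.random(net.n_nodes) * 10
        got = hrsv(net, 3, ordering="population_mean_strength",
                   population_strengths=pop).value
        want = oracles.hrsv(net.weights.tolist(), 3, True, basis=pop.tolist())
        assert got == pytest.approx(want, abs=1e-12)

    def test_window_bounds_rejected(self, k4):
        with pytest.raises(ValueError):
            hrsv(k4, 1)
        with pytest.raises(ValueError):
            hrsv(k4, 5)

    def test_regular_uniform_graph_zero_for_all_windows(self):
        import rsvnet
        net = rsvnet.generate(rsvnet.GeneratorSpec(
            family="regular", n=12, density=0.5, weight_model="uniform", seed=1))
        for w in (2, 4, 12):
            assert hrsv(net, w).value == pytest.approx(0.0, abs=1e-12)


class TestTiers:
    def test_85_nodes_4_tiers(self):
        basis = np.arange(85, dtype=float)
        tiers = assign_tiers(basis, 4)
        sizes = [int((tiers.tier_of_node == t).sum()) for t in (1, 2, 3, 4)]
        assert sizes == [22, 21, 21, 21]

    def test_even_split(self):
        tiers = assign_tiers(np.arange(8, dtype=float), 4)
        sizes = [int((tiers.tier_of_node == t).sum()) for t in (1, 2, 3, 4)]
        assert sizes == [2, 2, 2, 2]

    def test_top_strength_in_tier_1(self):
        basis = np.array([10.0, 9.0, 8.0, 7.0])
        tiers = assign_tiers(basis, 2)
        assert tiers.tier_of_node[0] == 1
        assert tiers.tier_of_node[-1] == 2

    def test_too_many_tiers_rejected(self):
        with pytest.raises(ValueError):
            assign_tiers(np.arange(3, dtype=float), 4)

    def test_tier_hrsv_matches_brute_force(self):
        rng = np.random.default_rng(17)
        W = np.where(rng.random((12, 12)) < 0.7, rng.integers(1, 4, (12, 12)), 0)
        W = np.triu(W, 1).astype(float)
        W += W.T
        net = WeightedNetwork.from_matrix(W)
        s = node_strengths(net)
        tiers = assign_tiers(s, 4)
        results = tier_hrsv(net, tiers, window_size=2)
        r_all = relative_strengths(net).r
        for t in (1, 2, 3, 4):
            nodes = tiers.nodes_in_tier(t)
            order = nodes[np.argsort(s[nodes], kind="stable")]
            vals = r_all[order]
            sds = [oracles.sample_sd(vals[k:k + 2].tolist())
                   for k in range(len(vals) - 1)]
            assert results[t].value == pytest.approx(sum(sds) / len(sds), abs=1e-12)

    def test_tier_of_window_size_has_single_window(self, k4):
        tiers = assign_tiers(node_strengths(k4), 2)
        res = tier_hrsv(k4, tiers, window_size=2)
        assert all(len(r.per_window) == 1 for r in res.values())
        assert all(r.value == pytest.approx(0.0, abs=1e-14) for r in res.values())

    def test_tier_smaller_than_window_rejected(self, k4):
        tiers = assign_tiers(node_strengths(k4), 2)
        with pytest.raises(ValueError, match="tier"):
            tier_hrsv(k4, tiers, window_size=3)
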