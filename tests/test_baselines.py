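"""Comparator filters: disparity, bistochastic, threshold, maximum spanning tree."""

import itertools
import math

import networkx as nx
import numpy as np
import pytest
from scipy import integrate

from lans import (
    WeightedNetwork,
    bistochastic_backbone,
    disparity_backbone,
    disparity_significance,
    fractional_weights,
    max_spanning_tree,
    random_weighted,
    simple_star,
    sinkhorn_matrix,
    sinkhorn_scale,
    threshold_backbone,
)


def single_node_fw(weights):
    net = WeightedNetwork(directed=True)
    for j, w in enumerate(weights):
        net.add_edge("a", f"x{j}", float(w))
    return fractional_weights(net)


class TestDisparitySignificance:
    def test_closed_form_values(self):
        fw = single_node_fw([1, 1, 2])  # p = 0.25, 0.25, 0.5; k = 3
        sig = disparity_significance(fw)
        assert math.isclose(sig[("a", "x2")], 0.25)  # (1 - 0.5)^2
        assert math.isclose(sig[("a", "x0")], 0.75 ** 2)

    def test_hub_of_simple_star(self):
        fw = single_node_fw([2.0] * 20)  # p = 1/20 each, k = 20
        sig = disparity_significance(fw)
        assert math.isclose(sig[("a", "x0")], 0.95 ** 19)

    def test_extreme_fraction_always_significant(self):
        fw = single_node_fw([1e9, 1e-9])
        sig = disparity_significance(fw)
        assert sig[("a", "x0")] < 1e-8

    def test_degree_one_never_significant(self):
        sig = disparity_significance(single_node_fw([4.2]))
        assert sig[("a", "x0")] == 1.0

    @pytest.mark.parametrize("k", [2, 3, 5, 10, 25, 50])
    def test_matches_quadrature_of_null_density(self, k):
        # null density of one stick-breaking weight: (k-1)(1-x)^(k-2)
        for p in np.linspace(0.02, 0.98, 13):
            tail, _ = integrate.quad(lambda x: (k - 1) * (1 - x) ** (k - 2), p, 1.0)
            assert math.isclose(tail, (1 - p) ** (k - 1), abs_tol=1e-10)


class TestDisparityBackbone:
    def test_simple_star_disconnects_at_005(self, star):
        net, _ = star
        bb = disparity_backbone(net, alpha=0.05)
        assert bb.n_kept == 0
        assert len(bb.isolated_nodes()) == net.n_nodes

    def test_simple_star_spokes_at_030(self, star):
        # outer-node spoke tail 0.25 < 0.30 <= hub 0.95^19, ring 0.75^2
        net, red = star
        bb = disparity_backbone(net, alpha=0.30)
        assert bb.kept_edges == red

    def test_monotone_in_alpha(self):
        net = random_weighted(30, 0.4, seed=2)
        prev = set()
        for a in (0.05, 0.2, 0.5, 0.9):
            kept = disparity_backbone(net, alpha=a).kept_edges
            assert prev <= kept
            prev = kept

    def test_agrees_with_lans_on_per_node_top_edge(self):
        # with distinct weights, both filters rank each node's largest
        # fraction as most significant
        net = random_weighted(20, 0.5, seed=8, directed=True)
        fw = fractional_weights(net)
        dsig = disparity_significance(fw)
        from lans import empirical_significance

        esig = empirical_significance(fw)
        for i in fw.p:
            best_d = min(fw.p[i], key=lambda j: dsig[(i, j)])
            best_e = min(fw.p[i], key=lambda j: esig.q[(i, j)])
            assert fw.p[i][best_d] == max(fw.p[i].values())
            assert fw.p[i][best_e] == max(fw.p[i].values())


class TestSinkhorn:
    def test_2x2_closed_form(self):
        m, r, c, converged, _ = sinkhorn_matrix(np.array([[2.0, 1.0], [1.0, 2.0]]))
        assert converged
        assert np.allclose(m, [[2 / 3, 1 / 3], [1 / 3, 2 / 3]], atol=1e-7)

    def test_doubly_stochastic_fixed_point(self):
        a = np.array([[0.5, 0.5], [0.5, 0.5]])
        m, _, _, converged, iters = sinkhorn_matrix(a)
        assert converged and iters == 0
        assert np.array_equal(m, a)

    def test_zero_row_rejected(self):
        with pytest.raises(ValueError, match="zero rows"):
            sinkhorn_matrix(np.array([[0.0, 0.0], [1.0, 2.0]]))

    def test_factors_reconstruct_scaling(self):
        rng = np.random.default_rng(0)
        a = rng.uniform(0.1, 5.0, size=(6, 6))
        m, r, c, converged, _ = sinkhorn_matrix(a, tol=1e-10)
        assert converged
        assert np.allclose(np.diag(r) @ a @ np.diag(c), m, rtol=1e-12)

    def test_residual_within_tol_on_network(self, star):
        net, _ = star
        scaling = sinkhorn_scale(net, tol=1e-8)
        assert scaling.converged
        assert scaling.max_residual() <= 1e-8
        assert all(b > 0 for b in scaling.b.values())

    def test_augmentation_rescues_unsupported_pattern(self):
        # rows a, b both positive only in column c: no positive diagonal
        # exists, so plain Sinkhorn cannot converge
        net = WeightedNetwork(directed=True)
        for u, v in [("a", "c"), ("b", "c"), ("c", "a"), ("c", "b"),
                     ("c", "d"), ("d", "c")]:
            net.add_edge(u, v, 1.0)
        plain = sinkhorn_scale(net, max_iter=500)
        assert not plain.converged
        fixed = sinkhorn_scale(net, max_iter=20_000, epsilon=1e-6)
        assert fixed.converged and fixed.epsilon_applied == 1e-6


class TestBistochasticBackbone:
    def test_budget_takes_top_edges_by_transformed_weight(self, triangle):
        scaling = sinkhorn_scale(triangle)
        order = sorted(scaling.b, key=scaling.b.get, reverse=True)
        bb = bistochastic_backbone(triangle, edge_budget=2)
        assert bb.kept_edges == set(order[:2])

    def test_simple_star_budget_returns_ring(self, star):
        net, red = star
        bb = bistochastic_backbone(net, edge_budget=20)
        assert bb.kept_edges == set(net.edge_dict()) - red

    def test_threshold_one_empty(self, star):
        # entries of a doubly stochastic matrix never exceed 1
        net, _ = star
        bb = bistochastic_backbone(net, weight_threshold=1.0)
        assert bb.n_kept == 0

    def test_exactly_one_stopping_rule(self, star):
        net, _ = star
        with pytest.raises(ValueError, match="exactly one"):
            bistochastic_backbone(net)
        with pytest.raises(ValueError, match="exactly one"):
            bistochastic_backbone(net, edge_budget=5, weight_threshold=0.1)

    def test_budget_cannot_exceed_edges(self, star):
        net, _ = star
        with pytest.raises(ValueError, match="budget"):
            bistochastic_backbone(net, edge_budget=1000)

    def test_nonconvergence_without_epsilon_raises(self):
        net = WeightedNetwork(directed=True)
        for u, v in [("a", "c"), ("b", "c"), ("c", "a"), ("c", "b"),
                     ("c", "d"), ("d", "c")]:
            net.add_edge(u, v, 1.0)
        with pytest.raises(RuntimeError, match="epsilon"):
            bistochastic_backbone(net, edge_budget=3, max_iter=500)


class TestThresholdBackbone:
    def test_simple_star_threshold_keeps_spokes(self, star):
        net, red = star
        assert threshold_backbone(net, 1.5).kept_edges == red

    def test_zero_threshold_keeps_all(self, star):
        net, _ = star
        assert threshold_backbone(net, 0.0).kept_edges == set(net.edge_dict())

    def test_complex_star_single_scale_failure(self, cstar):
        """A hard threshold cannot serve both weight scales at once."""
        net, _ = cstar
        low = threshold_backbone(net, 1.5)
        # 1.5 keeps everything central plus peripheral spokes, drops
        # peripheral rings only
        kept_w = {net.weight(u, v) for u, v in low.kept_edges}
        assert kept_w == {200.0, 100.0, 2.0}
        # 50 strands all 100 peripheral ring nodes (only the weight-100
        # connectors to the peripheral hubs survive out there), and 150
        # strands every peripheral node outright
        high = threshold_backbone(net, 50.0)
        stranded = {u for u in high.isolated_nodes() if u.startswith("p")}
        assert stranded == {u for u in net.nodes if "r" in u and u.startswith("p")}
        assert len(stranded) == 100
        top = threshold_backbone(net, 150.0)
        assert len([u for u in top.isolated_nodes() if u.startswith("p")]) == 110


def brute_force_max_tree_weight(net):
    g = net.to_networkx()
    n = net.n_nodes
    best = -math.inf
    for combo in itertools.combinations(list(net.edges()), n - 1):
        sub = nx.Graph()
        sub.add_nodes_from(net.nodes)
        sub.add_edges_from((u, v) for u, v, _ in combo)
        if nx.is_connected(sub):
            best = max(best, sum(w for _, _, w in combo))
    return best


class TestMaxSpanningTree:
    def test_triangle(self, triangle):
        bb = max_spanning_tree(triangle)
        assert bb.kept_edges == {("a", "b"), ("b", "c")}
        assert sum(bb.edge_score.values()) == 5.0

    def test_simple_star_matches_exhaustive(self):
        net, _ = simple_star(5)
        bb = max_spanning_tree(net)
        total = sum(net.weight(*e) for e in bb.kept_edges)
        assert bb.n_kept == net.n_nodes - 1
        assert total == brute_force_max_tree_weight(net)

    def test_random_graphs_match_exhaustive(self):
        rng = np.random.default_rng(123)
        trials = 0
        while trials < 40:
            n = int(rng.integers(4, 8))
            net = random_weighted(n, 0.7, seed=int(rng.integers(2 ** 31)))
            g = net.to_networkx()
            if net.n_edges < n - 1 or not nx.is_connected(g):
                continue
            trials += 1
            bb = max_spanning_tree(net)
            total = sum(net.weight(*e) for e in bb.kept_edges)
            assert math.isclose(total, brute_force_max_tree_weight(net), rel_tol=1e-12)

    def test_equal_weights_any_tree(self):
        net = WeightedNetwork()
        for u, v in itertools.combinations("abcde", 2):
            net.add_edge(u, v, 2.0)
        bb = max_spanning_tree(net)
        assert bb.n_kept == 4
        assert sum(net.weight(*e) for e in bb.kept_edges) == 8.0

    def test_disconnected_gives_forest(self):
        net = WeightedNetwork()
        net.add_edge("a", "b", 1.0)
        net.add_edge("c", "d", 1.0)
        bb = max_spanning_tree(net)
        assert bb.kept_edges == {("a", "b"), ("c", "d")}
        assert bb.params["n_components"] == 2

    def test_directed_rejected(self):
        net = WeightedNetwork(directed=True)
        net.add_edge("a", "b", 1.0)
        with pytest.raises(ValueError, match="undirected"):
            max_spanning_tree(net)
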