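import math

import networkx as nx
import numpy as np
import pytest

from dimona import (
    LayerNetwork,
    ReductionSpec,
    correlation_network,
    fit_scale_free_r2,
    harmonize_scale_free,
    reduce_network,
)
from conftest import make_matrix


def weights_of(net):
    return {frozenset((u, v)): w for u, v, w in net.graph.edges(data="weight")}


class TestCorrelationNetwork:
    def test_spearman_worked_values(self):
        m = make_matrix(
            [[1, 2, 3, 4], [2, 4, 6, 8], [4, 3, 2, 1], [1, 3, 2, 4]],
            features=["f1", "f2", "f3", "f4"],
        )
        net = correlation_network(m, min_pairs=3)
        w = weights_of(net)
        assert w[frozenset(("f1", "f2"))] == pytest.approx(1.0)
        assert w[frozenset(("f1", "f3"))] == pytest.approx(-1.0)
        # rank displacement d = (0,1,1,0): 1 - 6*2/(4*15) = 0.8
        assert w[frozenset(("f1", "f4"))] == pytest.approx(0.8)

    def test_pairwise_complete_observations(self):
        m = make_matrix([[1, 2, np.nan, 4], [2, 4, 6, 8]])
        net = correlation_network(m, min_pairs=3)
        assert weights_of(net)[frozenset(("f1", "f2"))] == pytest.approx(1.0)

    def test_min_pairs_drops_sparse_pair(self):
        m = make_matrix([[1, np.nan, np.nan, 4], [2, 4, 6, 8], [1, 2, 3, 4]])
        net = correlation_network(m, min_pairs=3)
        w = weights_of(net)
        assert frozenset(("f1", "f2")) not in w
        assert frozenset(("f2", "f3")) in w

    def test_zero_variance_feature_has_no_edges(self):
        m = make_matrix([[5, 5, 5, 5, 5], [1, 2, 3, 4, 5], [2, 1, 4, 3, 5]])
        net = correlation_network(m)
        assert net.graph.degree("f1") == 0
        assert net.graph.has_edge("f2", "f3")

    def test_spearman_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(size=(5, 12))
        base = correlation_network(make_matrix(vals))
        transformed = vals.copy()
        transformed[2] = np.exp(transformed[2])  # monotone on one feature
        trans = correlation_network(make_matrix(transformed))
        for k, w in weights_of(base).items():
            assert weights_of(trans)[k] == pytest.approx(w)

    def test_too_few_features_rejected(self):
        with pytest.raises(ValueError):
            correlation_network(make_matrix([[1, 2, 3]]))


def toy_net(abs_weights):
    """4-node network over the given |weights| with alternating signs."""
    g = nx.Graph()
    nodes = ["a", "b", "c", "d"]
    pairs = [(u, v) for i, u in enumerate(nodes) for v in nodes[i + 1 :]]
    for (u, v), w, s in zip(pairs, abs_weights, [1, -1] * 3):
        g.add_edge(u, v, weight=s * w)
    return LayerNetwork("protein", "A", g)


class TestReduceNetwork:
    def test_average_degree_keeps_top_count(self):
        net = toy_net([0.9, 0.8, 0.7, 0.6, 0.5, 0.4])
        red = reduce_network(net, ReductionSpec(method="average_degree", target_degree=2))
        kept = weights_of(red)
        assert len(kept) == 4  # round(4 * 2 / 2)
        assert all(abs(w) >= 0.6 for w in kept.values())

    def test_density_full_is_identity(self):
        net = toy_net([0.9, 0.8, 0.7, 0.6, 0.5, 0.4])
        red = reduce_network(net, ReductionSpec(method="density", target_density=1.0))
        assert weights_of(red) == weights_of(net)

    def test_density_half_keeps_three(self):
        net = toy_net([0.9, 0.8, 0.7, 0.6, 0.5, 0.4])
        red = reduce_network(net, ReductionSpec(method="density", target_density=0.5))
        assert red.n_edges == 3

    def test_ties_at_cut_all_kept(self):
        net = toy_net([0.9, 0.6, 0.6, 0.6, 0.5, 0.4])
        red = reduce_network(net, ReductionSpec(method="average_degree", target_degree=1))
        # target count 2 falls inside the 0.6 tie block -> all ties kept
        assert red.n_edges == 4

    def test_retained_weights_unchanged(self):
        net = toy_net([0.9, 0.8, 0.7, 0.6, 0.5, 0.4])
        red = reduce_network(net, ReductionSpec(method="density", target_density=0.5))
        full = weights_of(net)
        for k, w in weights_of(red).items():
            assert w == full[k]

    def test_overshooting_target_warns_and_keeps_all(self):
        net = toy_net([0.9, 0.8, 0.7, 0.6, 0.5, 0.4])
        with pytest.warns(UserWarning, match="keeping all"):
            red = reduce_network(
                net, ReductionSpec(method="average_degree", target_degree=10)
            )
        assert red.n_edges == net.n_edges

    def test_raising_cut_nests_edge_sets(self):
        rng = np.random.default_rng(5)
        g = nx.gnp_random_graph(15, 0.5, seed=2)
        for u, v in g.edges:
            g.edges[u, v]["weight"] = rng.uniform(-1, 1)
        net = LayerNetwork("protein", "A", g)
        prev = None
        for dens in [0.4, 0.3, 0.2, 0.1, 0.05]:
            red = reduce_network(net, ReductionSpec(method="density", target_density=dens))
            edges = set(weights_of(red))
            if prev is not None:
                assert edges <= prev
            prev = edges


class TestScaleFreeFit:
    def test_perfect_power_law(self):
        r2, slope = fit_scale_free_r2({1: 8, 2: 4, 4: 2, 8: 1})
        assert r2 == pytest.approx(1.0)
        assert slope == pytest.approx(-1.0)

    def test_single_bin_undefined(self):
        with pytest.raises(ValueError):
            fit_scale_free_r2({4: 10})

    def test_positive_slope_signed_negative(self):
        r2, slope = fit_scale_free_r2({1: 1, 2: 4, 4: 16})
        assert r2 == pytest.approx(-1.0)
        assert slope > 0


class TestHarmonize:
    def grid_spec(self, r2_target=0.5):
        return ReductionSpec(
            method="scale_free",
            r2_target=r2_target,
            threshold_grid=(0.2, 0.4, 0.6, 0.8),
        )

    @staticmethod
    def hub_net(condition, scale=1.0):
        """Star-plus-chain topology whose degree histogram fits a power law."""
        g = nx.Graph()
        rng = np.random.default_rng(11)
        hub = "h"
        for i in range(12):
            g.add_edge(hub, f"n{i}", weight=scale * rng.uniform(0.3, 0.95))
        for i in range(6):
            g.add_edge(f"n{i}", f"n{i+6}", weight=scale * rng.uniform(0.3, 0.95))
        return LayerNetwork("protein", condition, g)

    def test_identical_networks_symmetric(self):
        a, b = self.hub_net("A"), self.hub_net("B")
        cutA, cutB, redA, redB = harmonize_scale_free(a, b, self.grid_spec(0.3))
        assert cutA == cutB
        assert redA.n_edges == redB.n_edges

    def test_minimizes_edge_count_gap(self):
        a, b = self.hub_net("A"), self.hub_net("B", scale=0.9)
        spec = self.grid_spec(0.3)
        cutA, cutB, redA, redB = harmonize_scale_free(a, b, spec)
        # independent exhaustive search over the same grid
        from dimona.layers import _apply_cut, _network_signed_r2

        best = None
        for ca in spec.threshold_grid:
            ra = _apply_cut(a, ca)
            if _network_signed_r2(ra) < spec.r2_target:
                continue
            for cb in spec.threshold_grid:
                rb = _apply_cut(b, cb)
                if _network_signed_r2(rb) < spec.r2_target:
                    continue
                gap = abs(ra.n_edges - rb.n_edges)
                if best is None or gap < best:
                    best = gap
        assert best is not None
        assert abs(redA.n_edges - redB.n_edges) == best

    def test_relaxes_when_no_pair_qualifies(self):
        # condition A's random graph never reaches the 0.8 fit target at any
        # grid cut, so the target must relax before a pair qualifies
        rng = np.random.default_rng(4)
        g = nx.gnp_random_graph(30, 0.4, seed=9)
        for u, v in g.edges:
            g.edges[u, v]["weight"] = rng.uniform(0.1, 0.99)
        a = LayerNetwork("protein", "A", g)
        b = self.hub_net("B")
        with pytest.warns(UserWarning, match="relaxing"):
            cutA, cutB, redA, redB = harmonize_scale_free(a, b, self.grid_spec(0.8))
        assert cutA in (0.2, 0.4, 0.6, 0.8)
        assert redA.n_edges > 0 and redB.n_edges > 0

    def test_different_layers_rejected(self):
        a = self.hub_net("A")
        b = LayerNetwork("mrna", "B", a.graph.copy())
        with pytest.raises(ValueError):
            harmonize_scale_free(a, b, self.grid_spec())
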