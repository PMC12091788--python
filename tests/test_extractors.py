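"""Unit tests for the eight extraction methods on hand-checkable graphs."""

import math

import networkx as nx
import pytest

from netbackbone.graph import WeightedGraph, to_distance
from netbackbone.extractors import (
    DSInfeasibleError,
    compute_h_index_sets,
    compute_salience,
    compute_shortest_path_summary,
    extract,
    extract_ds,
    extract_hb,
    extract_hss,
    extract_mb,
    extract_msp,
    extract_plam,
    extract_pmfg,
    extract_umb,
    sinkhorn_normalize,
)

from conftest import random_graph


class TestMSP:
    def test_triangle_max_tree(self, triangle):
        b = extract_msp(triangle)
        assert b.kept_edges == {("a", "b"), ("b", "c")}
        assert sum(triangle.edges[e] for e in b.kept_edges) == 5.0
        assert b.kept_nodes == set(triangle.nodes)

    def test_tree_input_returned_unchanged(self):
        g = WeightedGraph({("a", "b"): 2, ("b", "c"): 7, ("b", "d"): 1})
        assert extract_msp(g).kept_edges == g.edge_set

    def test_disjoint_components_each_spanned(self, small_graphs):
        b = extract_msp(small_graphs["two_triangles"])
        assert b.kept_edges == {("a", "b"), ("b", "c"), ("x", "y"), ("y", "z")}


class TestPLAM:
    def test_triangle_per_node_maxima(self, triangle):
        # a and b both pick ab (weight 3); c picks bc (weight 2)
        assert extract_plam(triangle).kept_edges == {("a", "b"), ("b", "c")}

    def test_star_leaves_force_all_edges(self, small_graphs):
        g = small_graphs["star6_distinct"]
        assert extract_plam(g).kept_edges == g.edge_set

    def test_isolated_node_not_kept(self):
        g = WeightedGraph({("a", "b"): 1.0}, nodes=["z"])
        b = extract_plam(g)
        assert "z" not in b.kept_nodes

    def test_tie_goes_to_smallest_partner(self):
        g = WeightedGraph({("m", "a"): 5.0, ("m", "b"): 5.0})
        b = extract_plam(g)
        # m's two incident edges tie; ("a","m") < ("b","m") lexicographically,
        # but both edges stay because a and b each keep their only edge
        assert b.kept_edges == g.edge_set
        g2 = WeightedGraph({("m", "a"): 5.0, ("m", "b"): 5.0, ("a", "b"): 1.0})
        assert ("a", "m") in extract_plam(g2).kept_edges


class TestPMFG:
    def test_planar_input_unchanged(self):
        g = random_graph(3, n_lo=6, n_hi=6, p_lo=0.4, p_hi=0.4)
        planar, _ = nx.check_planarity(g.to_nx())
        if planar:
            assert extract_pmfg(g).kept_edges == g.edge_set

    def test_k4_all_kept(self):
        nodes = "abcd"
        g = WeightedGraph({(u, v): i + 1 for i, (u, v) in enumerate(
            (u, v) for i, u in enumerate(nodes) for v in nodes[i + 1:])})
        assert extract_pmfg(g).kept_edges == g.edge_set

    def test_k5_drops_exactly_minimum_weight_edge(self, small_graphs):
        g = small_graphs["k5_distinct"]
        b = extract_pmfg(g)
        wmin = min(g.edges, key=g.edges.get)
        assert len(b.kept_edges) == 9
        assert b.kept_edges == g.edge_set - {wmin}

    def test_complete_graph_reaches_planar_bound(self):
        n = 8
        edges = {(f"n{i}", f"n{j}"): float(i * n + j + 1)
                 for i in range(n) for j in range(i + 1, n)}
        b = extract_pmfg(WeightedGraph(edges))
        assert len(b.kept_edges) == 3 * (n - 2)
        assert nx.check_planarity(b.to_nx())[0]


class TestHIndex:
    def test_weights_5431(self):
        g = WeightedGraph({("a", "b"): 5, ("b", "c"): 4, ("c", "d"): 3, ("d", "e"): 1})
        res = compute_h_index_sets(g)
        assert res.h_strength == 3
        assert res.strength_edges == {("a", "b"), ("b", "c"), ("c", "d")}

    def test_all_weights_below_one(self):
        g = WeightedGraph({("a", "b"): 0.5, ("b", "c"): 0.9})
        res = compute_h_index_sets(g)
        assert res.h_strength == 0 and res.strength_edges == frozenset()

    def test_single_edge_weight_one(self):
        g = WeightedGraph({("a", "b"): 1.0})
        res = compute_h_index_sets(g)
        assert res.h_strength == 1 and res.strength_edges == {("a", "b")}

    def test_bridge_values_are_betweenness_over_n(self):
        g = WeightedGraph({("a", "b"): 1, ("b", "c"): 1, ("c", "d"): 1})
        res = compute_h_index_sets(g, betweenness_variant="unweighted")
        # middle edge bc carries pairs (a,c),(a,d),(b,c),(b,d) -> 4/4 = 1
        assert res.bridge_value[("b", "c")] == pytest.approx(1.0)
        assert res.bridge_value[("a", "b")] == pytest.approx(0.75)


class TestHB:
    def test_uniform_path_keeps_everything(self):
        g = WeightedGraph({("a", "b"): 3, ("b", "c"): 3, ("c", "d"): 3})
        assert extract_hb(g).kept_edges == g.edge_set

    def test_strength_only_when_bridges_weak(self, triangle):
        res = compute_h_index_sets(triangle)
        assert res.h_bridge == 0  # K3: each edge carries 1 pair -> 1/3 < 1
        assert extract_hb(triangle).kept_edges == res.strength_edges

    def test_empty_edge_graph(self):
        g = WeightedGraph({("a", "b"): 0.2})
        b = extract_hb(g)
        assert b.kept_edges == frozenset() and b.kept_nodes == frozenset()


class TestShortestPathSummary:
    def test_unit_path(self, small_graphs):
        s = compute_shortest_path_summary(to_distance(small_graphs["path_abc_unit"]))
        assert s.pair_distance[("a", "c")] == pytest.approx(2.0)
        assert s.minimax_distance[("a", "c")] == pytest.approx(1.0)

    def test_triangle_indirect_route(self, triangle):
        s = compute_shortest_path_summary(to_distance(triangle))
        assert s.pair_distance[("a", "c")] == pytest.approx(1 / 3 + 1 / 2)
        assert s.minimax_distance[("a", "c")] == pytest.approx(1 / 2)

    def test_direct_edge_bounds_pair_distance(self):
        g = random_graph(17, n_lo=8, n_hi=15)
        dv = to_distance(g)
        s = compute_shortest_path_summary(dv)
        for e, d in dv.distance.items():
            assert s.pair_distance[e] <= d + 1e-12

    def test_disconnected_pairs_infinite(self, small_graphs):
        s = compute_shortest_path_summary(to_distance(small_graphs["two_triangles"]))
        assert math.isinf(s.pair_distance[("a", "x")])
        assert math.isinf(s.minimax_distance[("a", "x")])


class TestMB:
    def test_triangle_semi_metric_edge_removed(self, triangle):
        # d_ac = 1 but the a-b-c route costs 1/3 + 1/2 < 1
        assert extract_mb(triangle).kept_edges == {("a", "b"), ("b", "c")}

    def test_tree_fully_metric(self):
        g = WeightedGraph({("a", "b"): 2, ("b", "c"): 9, ("b", "d"): 1})
        assert extract_mb(g).kept_edges == g.edge_set

    def test_uniform_triangle_kept(self):
        g = WeightedGraph({("a", "b"): 2, ("b", "c"): 2, ("a", "c"): 2})
        assert extract_mb(g).kept_edges == g.edge_set

    def test_preserves_all_shortest_path_distances(self):
        g = random_graph(5, n_lo=8, n_hi=14, p_lo=0.4, p_hi=0.8)
        full = compute_shortest_path_summary(to_distance(g)).pair_distance
        sub = extract_mb(g).to_graph()
        red = compute_shortest_path_summary(to_distance(sub)).pair_distance
        for pair, d in full.items():
            assert red[pair] == pytest.approx(d)


class TestUMB:
    def test_triangle_bottleneck_edge_removed(self, triangle):
        # max(1/3, 1/2) < 1, so ac is not on any minimax path
        assert extract_umb(triangle).kept_edges == {("a", "b"), ("b", "c")}

    def test_tree_fully_ultrametric(self):
        g = WeightedGraph({("a", "b"): 2, ("b", "c"): 9, ("b", "d"): 1})
        assert extract_umb(g).kept_edges == g.edge_set

    @pytest.mark.parametrize("seed", range(8))
    def test_contains_msp(self, seed):
        g = random_graph(seed, n_lo=6, n_hi=25)
        assert extract_msp(g).kept_edges <= extract_umb(g).kept_edges


class TestSinkhorn:
    def test_single_edge_converges_to_one(self):
        g = WeightedGraph({("a", "b"): 7.0})
        s = sinkhorn_normalize(g)
        assert s.converged and s.iterations == 1
        assert s.normalized_weight[("a", "b")] == pytest.approx(1.0)

    def test_path_is_infeasible_not_crash(self, small_graphs):
        # rows a and c both put all mass on column b: no doubly stochastic
        # matrix exists with this support
        s = sinkhorn_normalize(small_graphs["path_abc_unit"], max_iter=2000)
        assert not s.converged
        assert s.residual > 0.1

    @pytest.mark.parametrize("n", [3, 4, 6])
    def test_uniform_complete_graph_fixed_point(self, n):
        nodes = [f"v{i}" for i in range(n)]
        g = WeightedGraph({(u, v): 2.0 for i, u in enumerate(nodes)
                           for v in nodes[i + 1:]})
        s = sinkhorn_normalize(g)
        assert s.converged
        for sc in s.normalized_weight.values():
            assert sc == pytest.approx(1 / (n - 1))


class TestDS:
    def test_uniform_k3_lexicographic_tiebreak(self):
        g = WeightedGraph({("a", "b"): 1, ("a", "c"): 1, ("b", "c"): 1})
        assert extract_ds(g).kept_edges == {("a", "b"), ("a", "c")}

    def test_feasible_cycle_stops_when_connected(self):
        g = WeightedGraph({("a", "b"): 1, ("b", "c"): 1, ("c", "d"): 1, ("a", "d"): 1})
        b = extract_ds(g)
        assert b.params["infeasible"] is False
        assert nx.is_connected(b.to_nx())
        assert len(b.kept_edges) == 3  # spanning reached before the 4th edge

    def test_infeasible_policy(self, small_graphs):
        path = small_graphs["path_abc_unit"]
        b = extract_ds(path, max_iter=500)
        assert b.params["infeasible"] and b.kept_edges == frozenset()
        with pytest.raises(DSInfeasibleError):
            extract_ds(path, max_iter=500, on_failure="error")

    def test_stops_at_original_component_count(self):
        g = random_graph(11, n_lo=10, n_hi=20, p_lo=0.5, p_hi=0.9)
        b = extract_ds(g)
        if not b.params.get("infeasible"):
            assert (nx.number_connected_components(b.to_nx())
                    == nx.number_connected_components(g.to_nx()))


class TestSalienceHSS:
    def test_path_every_edge_salient(self, small_graphs):
        sal = compute_salience(to_distance(small_graphs["path_abc_unit"]))
        assert sal.salience == {("a", "b"): 1.0, ("b", "c"): 1.0}

    def test_triangle_salience_table(self, triangle):
        sal = compute_salience(to_distance(triangle)).salience
        assert sal == {("a", "b"): 1.0, ("b", "c"): 1.0, ("a", "c"): 0.0}

    def test_salience_values_are_count_fractions(self):
        g = random_graph(23, n_lo=6, n_hi=12)
        sal = compute_salience(to_distance(g))
        n = sal.n_roots
        for s in sal.salience.values():
            assert 0 <= s <= 1
            assert (s * n) == pytest.approx(round(s * n))

    def test_tree_salience_all_one(self):
        g = WeightedGraph({("a", "b"): 2, ("b", "c"): 9, ("b", "d"): 1, ("d", "e"): 4})
        b = extract_hss(g, threshold=1.0)
        assert b.kept_edges == g.edge_set

    def test_threshold_monotone(self):
        g = random_graph(31, n_lo=8, n_hi=16)
        assert (extract_hss(g, 1.0).kept_edges
                <= extract_hss(g, 0.9).kept_edges
                <= extract_hss(g, 0.5).kept_edges)

    def test_threshold_validation(self, triangle):
        for bad in (0.0, -0.1, 1.5):
            with pytest.raises(ValueError):
                extract_hss(triangle, threshold=bad)


def test_registry_dispatch(triangle):
    assert extract("MSP", triangle).kept_edges == extract_msp(triangle).kept_edges
    with pytest.raises(ValueError, match="unknown method"):
        extract("disparity", triangle)


def test_backbone_weights_are_parent_weights(triangle):
    for m in ("msp", "plam", "mb", "umb", "hss"):
        b = extract(m, triangle)
        for e, w in b.edge_weights().items():
            assert w == triangle.edges[e]
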