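"""Evaluation metrics: similarity, point-biserial, global properties, KS."""

import math

import numpy as np
import pytest
from scipy import stats

from netbackbone.graph import Backbone, WeightedGraph
from netbackbone.extractors import extract_msp
from netbackbone.metrics import (
    aggregate,
    edge_properties,
    global_properties,
    ks_statistic,
    pair_similarity,
    point_biserial,
    rank_methods,
)
from netbackbone import oracles

from conftest import random_graph


def _bb(parent, edges, method="x"):
    edges = frozenset(edges)
    nodes = frozenset(n for e in edges for n in e)
    return Backbone(method, parent, edges, nodes)


@pytest.fixture()
def four_path():
    return WeightedGraph(
        {("a", "b"): 1, ("b", "c"): 1, ("c", "d"): 1, ("a", "d"): 1}
    )


class TestPairSimilarity:
    def test_set_arithmetic(self, four_path):
        s = pair_similarity(
            _bb(four_path, [("a", "b"), ("b", "c")]),
            _bb(four_path, [("a", "b"), ("c", "d")]),
        )
        assert s.jaccard == pytest.approx(1 / 3)
        assert s.overlap_from_first == pytest.approx(1 / 2)
        assert s.overlap_from_second == pytest.approx(1 / 2)

    def test_identity_and_subset(self, four_path):
        b1 = _bb(four_path, [("a", "b")])
        b2 = _bb(four_path, [("a", "b"), ("b", "c"), ("c", "d")])
        same = pair_similarity(b1, b1)
        assert same.jaccard == same.overlap_from_first == 1.0
        sub = pair_similarity(b1, b2)
        assert sub.overlap_from_first == 1.0
        assert sub.jaccard == pytest.approx(1 / 3)

    def test_empty_sets_convention(self, four_path):
        s = pair_similarity(_bb(four_path, []), _bb(four_path, []))
        assert s.jaccard == 1.0

    def test_jaccard_bounded_by_overlaps(self):
        rng = np.random.default_rng(0)
        g = random_graph(2, n_lo=10, n_hi=20, p_lo=0.4, p_hi=0.8)
        edges = sorted(g.edge_set)
        for _ in range(50):
            e1 = [e for e in edges if rng.random() < 0.5]
            e2 = [e for e in edges if rng.random() < 0.5]
            s = pair_similarity(_bb(g, e1), _bb(g, e2))
            assert s.jaccard <= min(s.overlap_from_first, s.overlap_from_second) + 1e-15

    def test_different_parents_rejected(self, four_path, triangle):
        with pytest.raises(ValueError, match="different parent"):
            pair_similarity(_bb(four_path, []), _bb(triangle, []))


class TestAggregate:
    def test_population_std(self):
        a = aggregate([0.0, 1.0])
        assert a.mean == 0.5 and a.std == 0.5
        b = aggregate([0.2, 0.4, 0.6])
        assert b.mean == pytest.approx(0.4)
        assert b.std == pytest.approx(math.sqrt(0.08 / 3))
        c = aggregate([1.0, 1.0, 1.0])
        assert c.mean == 1.0 and c.std == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            aggregate([])


class TestEdgeProperties:
    def test_path_values(self, small_graphs):
        t = edge_properties(small_graphs["path_abc_unit"])
        assert t.loc[("a", "b"), "degree_product"] == 2  # 1 * 2
        assert t.loc[("a", "b"), "strength_product"] == pytest.approx(2.0)
        # pairs {a,b} and {a,c} route through ab -> 2 raw
        assert t.loc[("a", "b"), "betweenness"] == pytest.approx(2.0)

    def test_uniform_weights_betweenness_variants_agree(self):
        g = WeightedGraph({("a", "b"): 2, ("b", "c"): 2, ("c", "d"): 2, ("a", "d"): 2})
        t = edge_properties(g)
        assert np.allclose(t["betweenness"], t["weighted_betweenness"])

    def test_betweenness_matches_path_enumeration(self):
        g = random_graph(7, n_lo=5, n_hi=8, p_lo=0.4, p_hi=0.8)
        t = edge_properties(g)
        brute_u = oracles.brute_edge_betweenness(g, map_name=None)
        brute_w = oracles.brute_edge_betweenness(g, map_name="inverse")
        for e in g.edge_set:
            assert t.loc[e, "betweenness"] == pytest.approx(brute_u[e])
            assert t.loc[e, "weighted_betweenness"] == pytest.approx(brute_w[e])


class TestPointBiserial:
    def test_worked_example(self):
        r = point_biserial([1, 1, 0, 0], [4, 3, 2, 1])
        assert r == pytest.approx(0.8944271909999159, abs=1e-10)

    def test_degenerate_cases(self):
        assert math.isnan(point_biserial([1, 1, 1, 1], [1, 2, 3, 4]))
        assert math.isnan(point_biserial([1, 0, 1, 0], [2, 2, 2, 2]))

    def test_direction_positive_for_top_half(self):
        vals = np.arange(1.0, 21.0)
        presence = (vals > 10).astype(float)
        assert point_biserial(presence, vals) > 0

    def test_equals_pearson(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            n = int(rng.integers(4, 40))
            p = rng.integers(0, 2, n).astype(float)
            if p.sum() in (0, n):
                continue
            y = rng.normal(size=n)
            assert point_biserial(p, y) == pytest.approx(
                stats.pearsonr(p, y).statistic, abs=1e-12
            )


class TestGlobalProperties:
    def test_backbone_equal_parent_is_all_ones(self, four_path):
        b = _bb(four_path, four_path.edge_set)
        rep = global_properties(b)
        for p in ("edge_fraction", "node_fraction", "weight_fraction",
                  "weight_entropy", "reachability"):
            assert rep.normalized[p] == pytest.approx(1.0)

    def test_k3_single_edge(self, triangle):
        b = _bb(triangle, [("a", "b")])
        rep = global_properties(b)
        assert rep.raw["edge_fraction"] == pytest.approx(1 / 3)
        assert rep.raw["node_fraction"] == pytest.approx(2 / 3)
        assert rep.raw["reachability"] == pytest.approx(1 / 3)
        assert rep.raw["transitivity"] == 0.0
        assert rep.raw["n_components"] == 1

    def test_uniform_entropy_closed_form(self):
        g = WeightedGraph({("a", "b"): 2, ("b", "c"): 2, ("c", "d"): 2, ("a", "d"): 2})
        b = _bb(g, [("a", "b"), ("b", "c")])
        rep = global_properties(b)
        assert rep.raw["weight_entropy"] == pytest.approx(math.log(2))
        assert rep.normalized["weight_entropy"] == pytest.approx(
            math.log(2) / math.log(4)
        )

    def test_equal_weight_entropy_is_log_m(self):
        g = WeightedGraph({(f"a{i}", f"b{i}"): 3.0 for i in range(7)})
        rep = global_properties(_bb(g, g.edge_set))
        assert rep.raw["weight_entropy"] == pytest.approx(math.log(7))

    def test_spanning_connected_backbone_reachability_one(self):
        g = random_graph(13, n_lo=8, n_hi=20, p_lo=0.4, p_hi=0.9)
        import networkx as nx

        if nx.is_connected(g.to_nx()):
            rep = global_properties(extract_msp(g))
            assert rep.raw["reachability"] == pytest.approx(1.0)

    def test_undefined_normalization_reported_missing(self, small_graphs):
        # parent path has no triangles: original transitivity 0
        b = _bb(small_graphs["path_abc_unit"], [("a", "b")])
        rep = global_properties(b)
        assert math.isnan(rep.normalized["transitivity"])


class TestKS:
    def test_identical_and_disjoint(self):
        assert ks_statistic([1, 2, 3], [1, 2, 3]) == 0.0
        assert ks_statistic([1, 2], [5, 6]) == 1.0

    def test_nested_sample_gap(self):
        assert ks_statistic([1, 2], [1, 2, 3, 4]) == pytest.approx(0.5)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ks_statistic([], [1.0])

    def test_matches_bruteforce_ecdf(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            a = rng.normal(size=int(rng.integers(2, 60)))
            b = rng.normal(loc=rng.uniform(-1, 1), size=int(rng.integers(2, 60)))
            assert ks_statistic(a, b) == pytest.approx(oracles.brute_ks(a, b), abs=1e-12)


class TestRanks:
    def test_simple_order(self):
        assert rank_methods({"A": 0.1, "B": 0.3}) == {"A": 1.0, "B": 2.0}

    def test_average_rank_ties(self):
        got = rank_methods({"A": 0.1, "B": 0.2, "C": 0.2, "D": 0.5})
        assert got == {"A": 1.0, "B": 2.5, "C": 2.5, "D": 4.0}

    def test_full_tie(self):
        got = rank_methods({m: 0.4 for m in "ABCDE"})
        assert all(r == 3.0 for r in got.values())

    def test_requires_two_methods(self):
        with pytest.raises(ValueError):
            rank_methods({"A": 0.1})
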