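"""The eight structural backbone extraction methods.

Each extractor is a pure function ``WeightedGraph -> Backbone``:

================  ============================================================
``extract_msp``   Maximum spanning tree/forest: spans all nodes, maximizes
                  total retained weight.
``extract_pmfg``  Planar maximally filtered graph: greedily adds edges in
                  decreasing weight while the result stays planar.
``extract_plam``  Primary linkage analysis: each node keeps its single
                  strongest incident edge.
``extract_hb``    h-backbone: union of the h-strength network (h strongest
                  edges with weight ≥ h) and the h-bridge network (same
                  h-index applied to edge betweenness / N).
``extract_mb``    Metric backbone: edges whose direct distance equals the
                  minimal sum-of-distances path between their endpoints.
``extract_umb``   Ultrametric backbone: edges whose direct distance equals the
                  minimax (bottleneck) path distance.
``extract_ds``    Doubly stochastic filter: Sinkhorn-balance the weighted
                  adjacency matrix, then add edges by decreasing normalized
                  weight until the original connectivity is restored.
``extract_hss``   High salience skeleton: edges present in at least a fraction
                  ``threshold`` of per-root shortest-path trees.
================  ============================================================

Determinism: every sort uses the total order ``(criterion, min label,
max label)``, so results are reproducible and tie-breaking is explicit.
Distance-based methods record the weight→distance map in the backbone's
``params``.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .graph import Backbone, DistanceView, WeightedGraph, edge_key, to_distance

__all__ = [
    "extract_msp",
    "extract_pmfg",
    "extract_plam",
    "extract_hb",
    "extract_mb",
    "extract_umb",
    "extract_ds",
    "extract_hss",
    "extract",
    "EXTRACTORS",
    "compute_h_index_sets",
    "compute_shortest_path_summary",
    "compute_salience",
    "sinkhorn_normalize",
    "HIndexResult",
    "ShortestPathSummary",
    "SalienceScores",
    "StochasticScores",
    "DSInfeasibleError",
]

# Edge kept iff d_e <= D * (1 + REL_TOL) + ABS_TOL.  D <= d_e always holds for
# a direct edge, so only roundoff can separate genuinely equal values.
REL_TOL = 1e-9
ABS_TOL = 1e-12


def _metric_close(d_edge: float, d_path: float) -> bool:
    return d_edge <= d_path * (1.0 + REL_TOL) + ABS_TOL


# ---------------------------------------------------------------------------
# Spanning / ordering based methods
# ---------------------------------------------------------------------------


class _UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}
        self.n_components = len(self.parent)

    def find(self, x):
        p = self.parent
        root = x
        while p[root] != root:
            root = p[root]
        while p[x] != root:
            p[x], x = root, p[x]
        return root

    def union(self, a, b) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        self.parent[rb] = ra
        self.n_components -= 1
        return True


def _kruskal_forest(graph: WeightedGraph, ordered_edges) -> frozenset:
    """Spanning forest built by scanning ``ordered_edges`` (Kruskal)."""
    uf = _UnionFind(graph.nodes)
    kept = set()
    for e in ordered_edges:
        if uf.union(*e):
            kept.add(e)
    return frozenset(kept)


def _msp_order(graph: WeightedGraph):
    w = graph.edges
    return sorted(w, key=lambda e: (-w[e], e))


def extract_msp(graph: WeightedGraph) -> Backbone:
    """Maximum spanning forest: per component, a tree of maximal total weight."""
    kept = _kruskal_forest(graph, _msp_order(graph))
    return Backbone("msp", graph, kept, frozenset(graph.nodes))


def extract_plam(graph: WeightedGraph) -> Backbone:
    """Each node keeps its maximum-weight incident edge.

    Ties go to the lexicographically smallest partner.  Isolated nodes have
    no incident edge and are absent from the backbone.
    """
    w = graph.edges
    best: dict[str, tuple[str, str]] = {}
    # Scan edges in decreasing weight; the first edge seen per node wins, so
    # the secondary (min-label, max-label) key implements the tie-break.
    for e in _msp_order(graph):
        for node in e:
            if node not in best:
                best[node] = e
    kept = frozenset(best.values())
    nodes = frozenset(n for e in kept for n in e)
    return Backbone("plam", graph, kept, nodes)


def _planar_edge_bound(graph: WeightedGraph) -> int:
    """Max edges of a planar graph with this component structure."""
    bound = 0
    for comp in nx.connected_components(graph.to_nx()):
        c = len(comp)
        bound += 0 if c == 1 else (1 if c == 2 else 3 * c - 6)
    return bound


def extract_pmfg(graph: WeightedGraph) -> Backbone:
    """Greedy planar filter: scan edges by decreasing weight, keep each edge
    iff the accumulated subgraph stays planar.

    The scan stops early once the planar edge bound (3(n_c − 2) summed over
    components with n_c ≥ 3) is reached, since no further edge can be added.
    """
    bound = _planar_edge_bound(graph)
    acc = nx.Graph()
    acc.add_nodes_from(graph.nodes)
    kept: set = set()
    for e in _msp_order(graph):
        if len(kept) >= bound:
            break
        acc.add_edge(*e)
        ok, _ = nx.check_planarity(acc, counterexample=False)
        if ok:
            kept.add(e)
        else:
            acc.remove_edge(*e)
    return Backbone("pmfg", graph, frozenset(kept), frozenset(graph.nodes))


# ---------------------------------------------------------------------------
# h-backbone
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HIndexResult:
    """h-strength / h-bridge decomposition used by the h-backbone."""

    h_strength: int
    h_bridge: int
    strength_edges: frozenset
    bridge_edges: frozenset
    bridge_value: dict


def _h_index(values) -> int:
    """Largest natural h such that at least h values are ≥ h."""
    h = 0
    for i, v in enumerate(sorted(values, reverse=True), start=1):
        if v >= i:
            h = i
        else:
            break
    return h


def compute_h_index_sets(
    graph: WeightedGraph,
    betweenness_variant: str = "weighted",
    map_name: str = "inverse",
) -> HIndexResult:
    """h-strength on raw weights and h-bridge on edge betweenness / N.

    ``betweenness_variant``: "weighted" routes shortest paths by distance sum
    on the chosen distance map; "unweighted" counts hops.  Betweenness is the
    raw (unnormalized) pair count with fractional credit for tied paths,
    divided by the node count N as the bridge value.  The weight comparison
    ``w ≥ h`` uses the raw real weight against the integer h, no rounding.
    """
    w = graph.edges
    h_s = _h_index(w.values())
    strength = frozenset(e for e, wt in w.items() if wt >= h_s) if h_s >= 1 else frozenset()
    if betweenness_variant == "weighted":
        g = to_distance(graph, map_name).to_nx()
        eb = nx.edge_betweenness_centrality(g, normalized=False, weight="distance")
    elif betweenness_variant == "unweighted":
        eb = nx.edge_betweenness_centrality(graph.to_nx(), normalized=False)
    else:
        raise ValueError(f"unknown betweenness_variant {betweenness_variant!r}")
    n = graph.n_nodes
    bridge_value = {edge_key(*e): b / n for e, b in eb.items()}
    h_b = _h_index(bridge_value.values())
    bridge = (
        frozenset(e for e, b in bridge_value.items() if b >= h_b) if h_b >= 1 else frozenset()
    )
    return HIndexResult(h_s, h_b, strength, bridge, bridge_value)


def extract_hb(
    graph: WeightedGraph,
    betweenness_variant: str = "weighted",
    map_name: str = "inverse",
) -> Backbone:
    """h-backbone: merge of the h-strength and h-bridge edge sets.

    Unlike the spanning methods, the h-backbone keeps only nodes incident to
    a kept edge, so it may isolate nodes.  It is deliberately not
    scale-invariant: h compares weights against natural numbers.
    """
    res = compute_h_index_sets(graph, betweenness_variant, map_name)
    kept = res.strength_edges | res.bridge_edges
    nodes = frozenset(n for e in kept for n in e)
    return Backbone(
        "hb",
        graph,
        kept,
        nodes,
        params={
            "h_strength": res.h_strength,
            "h_bridge": res.h_bridge,
            "betweenness_variant": betweenness_variant,
            "map": map_name,
        },
    )


# ---------------------------------------------------------------------------
# Shortest-path machinery (metric / ultrametric / salience)
# ---------------------------------------------------------------------------


def _adjacency(dist: DistanceView) -> dict[str, list[tuple[str, float]]]:
    adj: dict[str, list[tuple[str, float]]] = {n: [] for n in dist.parent.nodes}
    for (u, v), d in dist.distance.items():
        adj[u].append((v, d))
        adj[v].append((u, d))
    for lst in adj.values():
        lst.sort()
    return adj


def _dijkstra(adj, source) -> dict[str, float]:
    dist = {source: 0.0}
    heap = [(0.0, source)]
    done = set()
    while heap:
        d, u = heapq.heappop(heap)
        if u in done:
            continue
        done.add(u)
        for v, duv in adj[u]:
            nd = d + duv
            if nd < dist.get(v, math.inf):
                dist[v] = nd
                heapq.heappush(heap, (nd, v))
    return dist


def _minimax_dijkstra(adj, source) -> dict[str, float]:
    """Min over paths of the maximum edge distance (bottleneck distance)."""
    bott = {source: 0.0}
    heap = [(0.0, source)]
    done = set()
    while heap:
        b, u = heapq.heappop(heap)
        if u in done:
            continue
        done.add(u)
        for v, duv in adj[u]:
            nb = max(b, duv)
            if nb < bott.get(v, math.inf):
                bott[v] = nb
                heapq.heappush(heap, (nb, v))
    return bott


def _spt_edges(adj, source) -> set:
    """Union of all minimum-sum shortest paths from ``source``, as edges.

    An edge (p, v) belongs to the shortest-path tree of the root iff it lies
    on at least one minimum-sum path from the root, i.e. iff
    dist(p) + d(p, v) == dist(v) for some orientation.
    """
    dist = {source: 0.0}
    preds: dict[str, list[str]] = {source: []}
    heap = [(0.0, source)]
    done = set()
    while heap:
        d, u = heapq.heappop(heap)
        if u in done:
            continue
        done.add(u)
        for v, duv in adj[u]:
            nd = d + duv
            old = dist.get(v, math.inf)
            if nd < old and not math.isclose(nd, old, rel_tol=REL_TOL, abs_tol=ABS_TOL):
                dist[v] = nd
                preds[v] = [u]
                heapq.heappush(heap, (nd, v))
            elif math.isclose(nd, old, rel_tol=REL_TOL, abs_tol=ABS_TOL) and u not in preds.get(v, ()):
                preds.setdefault(v, []).append(u)
    return {edge_key(p, v) for v, ps in preds.items() for p in ps}


@dataclass(frozen=True)
class ShortestPathSummary:
    """All-pairs sum distances D, minimax distances U, and per-root
    shortest-path-tree edge membership (disconnected pairs get +inf)."""

    pair_distance: dict
    minimax_distance: dict
    spt_membership: dict


def compute_shortest_path_summary(dist: DistanceView) -> ShortestPathSummary:
    adj = _adjacency(dist)
    nodes = dist.parent.nodes
    pair: dict[tuple[str, str], float] = {}
    mini: dict[tuple[str, str], float] = {}
    spt: dict[str, frozenset] = {}
    for r in nodes:
        dd = _dijkstra(adj, r)
        bb = _minimax_dijkstra(adj, r)
        for v in nodes:
            if v <= r:
                continue
            pair[(r, v)] = dd.get(v, math.inf)
            mini[(r, v)] = bb.get(v, math.inf)
        spt[r] = frozenset(_spt_edges(adj, r))
    return ShortestPathSummary(pair, mini, spt)


def extract_mb(graph: WeightedGraph, map_name: str = "inverse") -> Backbone:
    """Metric backbone: keep edge (u, v) iff no indirect path has a strictly
    smaller sum of distances, i.e. d_uv equals the shortest-path distance.

    The backbone preserves every pairwise shortest-path distance of the
    original graph and spans all nodes.
    """
    dv = to_distance(graph, map_name)
    adj = _adjacency(dv)
    kept = set()
    done_sources: dict[str, dict] = {}
    for (u, v), d in dv.distance.items():
        if u not in done_sources:
            done_sources[u] = _dijkstra(adj, u)
        if _metric_close(d, done_sources[u][v]):
            kept.add((u, v))
    return Backbone("mb", graph, frozenset(kept), frozenset(graph.nodes),
                    params={"map": map_name})


def extract_umb(graph: WeightedGraph, map_name: str = "inverse") -> Backbone:
    """Ultrametric backbone: keep edge (u, v) iff its distance equals the
    minimax (bottleneck) path distance between u and v.

    The minimax distance is realized on a minimum-distance spanning forest,
    which (under a strictly decreasing map) is the maximum-weight spanning
    forest — hence MSP ⊆ UMB.
    """
    dv = to_distance(graph, map_name)
    d = dv.distance
    # Same ordered scan as MSP (strictly decreasing map preserves the order),
    # so the tree used here is exactly the MSP forest.
    tree = _kruskal_forest(graph, _msp_order(graph))
    # Root each component; record parent, parent-edge distance and depth.
    tadj: dict[str, list[str]] = {n: [] for n in graph.nodes}
    for u, v in tree:
        tadj[u].append(v)
        tadj[v].append(u)
    parent: dict[str, str | None] = {}
    pdist: dict[str, float] = {}
    depth: dict[str, int] = {}
    for root in graph.nodes:
        if root in parent:
            continue
        parent[root] = None
        pdist[root] = 0.0
        depth[root] = 0
        stack = [root]
        while stack:
            x = stack.pop()
            for y in tadj[x]:
                if y not in parent:
                    parent[y] = x
                    pdist[y] = d[edge_key(x, y)]
                    depth[y] = depth[x] + 1
                    stack.append(y)

    def path_max(u: str, v: str) -> float:
        m = 0.0
        while depth[u] > depth[v]:
            m = max(m, pdist[u])
            u = parent[u]
        while depth[v] > depth[u]:
            m = max(m, pdist[v])
            v = parent[v]
        while u != v:
            m = max(m, pdist[u], pdist[v])
            u, v = parent[u], parent[v]
        return m

    kept = set()
    for e, de in d.items():
        if e in tree or _metric_close(de, path_max(*e)):
            kept.add(e)
    return Backbone("umb", graph, frozenset(kept), frozenset(graph.nodes),
                    params={"map": map_name})


# ---------------------------------------------------------------------------
# Doubly stochastic filter
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StochasticScores:
    """Sinkhorn-balanced per-edge scores (mean of the two directed entries)."""

    normalized_weight: dict
    converged: bool
    iterations: int
    residual: float


class DSInfeasibleError(RuntimeError):
    """Sinkhorn balancing did not converge for this graph's support."""


def sinkhorn_normalize(
    graph: WeightedGraph, tol: float = 1e-8, max_iter: int = 10000
) -> StochasticScores:
    """Alternately normalize row and column sums of the weighted adjacency
    matrix until every row/column sum is within ``tol`` of 1.

    Balancing is restricted to non-isolated nodes (an all-zero row can never
    sum to 1).  Non-convergence is not an exception: a doubly stochastic
    matrix with the graph's support may simply not exist — the flag and the
    final residual are reported and the caller decides policy.
    """
    if graph.n_edges == 0:
        raise ValueError("sinkhorn_normalize requires at least one edge")
    active = sorted({n for e in graph.edge_set for n in e})
    idx = {n: i for i, n in enumerate(active)}
    n = len(active)
    a = np.zeros((n, n))
    for (u, v), wt in graph.edges.items():
        a[idx[u], idx[v]] = wt
        a[idx[v], idx[u]] = wt
    converged = False
    residual = math.inf
    it = 0
    for it in range(1, max_iter + 1):
        a /= a.sum(axis=1, keepdims=True)
        a /= a.sum(axis=0, keepdims=True)
        residual = max(
            np.abs(a.sum(axis=1) - 1.0).max(),
            np.abs(a.sum(axis=0) - 1.0).max(),
        )
        if residual < tol:
            converged = True
            break
    scores = {
        e: float(0.5 * (a[idx[e[0]], idx[e[1]]] + a[idx[e[1]], idx[e[0]]]))
        for e in graph.edge_set
    }
    return StochasticScores(scores, converged, it, float(residual))


def extract_ds(
    graph: WeightedGraph,
    tol: float = 1e-8,
    max_iter: int = 10000,
    on_failure: str = "skip",
) -> Backbone:
    """Doubly stochastic filter: sort edges by decreasing normalized weight
    and add them one at a time until the kept-edge graph has the same number
    of connected components (over the original node set) as the original —
    for a connected original, a single component spanning all nodes.

    When Sinkhorn balancing is infeasible: ``on_failure="error"`` raises
    :class:`DSInfeasibleError`; ``"skip"`` returns an empty backbone whose
    ``params`` carry ``infeasible=True``.
    """
    if on_failure not in ("error", "skip"):
        raise ValueError(f"unknown on_failure {on_failure!r}")
    scores = sinkhorn_normalize(graph, tol=tol, max_iter=max_iter)
    base = {"tol": tol, "max_iter": max_iter, "iterations": scores.iterations,
            "residual": scores.residual}
    if not scores.converged:
        if on_failure == "error":
            raise DSInfeasibleError(
                f"Sinkhorn balancing did not converge (residual {scores.residual:.3g})"
            )
        return Backbone("ds", graph, frozenset(), frozenset(),
                        params={**base, "infeasible": True})
    s = scores.normalized_weight
    target = nx.number_connected_components(graph.to_nx())
    uf = _UnionFind(graph.nodes)
    kept: set = set()
    score_map = {}
    for e in sorted(s, key=lambda e: (-s[e], e)):
        kept.add(e)
        score_map[e] = s[e]
        uf.union(*e)
        if uf.n_components == target:
            break
    nodes = frozenset(n for e in kept for n in e)
    return Backbone("ds", graph, frozenset(kept), nodes, score=score_map,
                    params={**base, "infeasible": False})


# ---------------------------------------------------------------------------
# High salience skeleton
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SalienceScores:
    """Fraction of per-root shortest-path trees containing each edge."""

    salience: dict
    n_roots: int


def compute_salience(dist: DistanceView) -> SalienceScores:
    """salience(e) = |{roots r : e ∈ SPT(r)}| / N, where SPT(r) is the union
    of all minimum-sum shortest paths from r."""
    adj = _adjacency(dist)
    n = dist.parent.n_nodes
    counts = {e: 0 for e in dist.distance}
    for r in dist.parent.nodes:
        for e in _spt_edges(adj, r):
            counts[e] += 1
    return SalienceScores({e: c / n for e, c in counts.items()}, n)


def extract_hss(
    graph: WeightedGraph, threshold: float = 0.9, map_name: str = "inverse"
) -> Backbone:
    """High salience skeleton: keep edges with salience ≥ ``threshold``.

    Salience is near-bimodal in real networks (mass near 0 and near 1), so
    the default threshold 0.9 captures the "near 1" mode.  Nodes not incident
    to a kept edge are dropped — the skeleton may isolate nodes.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError(f"threshold must lie in (0, 1], got {threshold!r}")
    sal = compute_salience(to_distance(graph, map_name))
    kept = frozenset(e for e, s in sal.salience.items() if s >= threshold)
    nodes = frozenset(n for e in kept for n in e)
    score = {e: sal.salience[e] for e in kept}
    return Backbone("hss", graph, kept, nodes, score=score,
                    params={"threshold": threshold, "map": map_name})


# ---------------------------------------------------------------------------
# Registry
# ---------------------------------------------------------------------------

EXTRACTORS = {
    "msp": extract_msp,
    "pmfg": extract_pmfg,
    "plam": extract_plam,
    "hb": extract_hb,
    "mb": extract_mb,
    "umb": extract_umb,
    "ds": extract_ds,
    "hss": extract_hss,
}


def extract(method: str, graph: WeightedGraph, **params) -> Backbone:
    """Dispatch to a registered extractor by name."""
    try:
        fn = EXTRACTORS[method.lower()]
    except KeyError:
        raise ValueError(f"unknown method {method!r}; choose from {sorted(EXTRACTORS)}")
    return fn(graph, **params)
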