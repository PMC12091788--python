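"""Brute-force reference computations.

Deliberately naive, exhaustive re-derivations of what the extractors compute,
kept independent of the production code paths so they can serve as oracles in
tests and for the golden fixtures: spanning-tree enumeration, Floyd–Warshall
metric closure, simple-path minimax enumeration, shortest-path-tree membership
via the distance condition, path-enumeration edge betweenness, a
Kuratowski-subdivision planarity test, and a free-standing Sinkhorn loop.
Only suitable for small graphs (roughly n ≤ 12).
"""

from __future__ import annotations

import itertools
import math

import numpy as np

from .graph import WeightedGraph, edge_key, to_distance

REL_TOL = 1e-9
ABS_TOL = 1e-12


def _close(a: float, b: float) -> bool:
    return a <= b * (1.0 + REL_TOL) + ABS_TOL


def _components(nodes, edges):
    nodes = list(nodes)
    parent = {n: n for n in nodes}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for u, v in edges:
        parent[find(u)] = find(v)
    comps = {}
    for n in nodes:
        comps.setdefault(find(n), set()).add(n)
    return list(comps.values())


def brute_max_spanning_forest(graph: WeightedGraph):
    """Maximum-total-weight spanning forest by exhaustive subset enumeration.

    Per connected component with c nodes, tries every edge subset of size
    c − 1 and keeps the spanning one of maximal weight.  Returns
    ``(edge set, total weight)``; the edge set is unique for distinct weights.
    """
    w = graph.edges
    best_edges: set = set()
    total = 0.0
    for comp in _components(graph.nodes, w):
        comp_edges = [e for e in w if e[0] in comp and e[1] in comp]
        c = len(comp)
        if c == 1:
            continue
        best = None
        for subset in itertools.combinations(comp_edges, c - 1):
            if len(_components(comp, subset)) == 1:
                wt = sum(w[e] for e in subset)
                if best is None or wt > best[1]:
                    best = (set(subset), wt)
        best_edges |= best[0]
        total += best[1]
    return best_edges, total


def floyd_warshall_closure(graph: WeightedGraph, map_name: str = "inverse"):
    """Metric backbone edge set via an exhaustive Floyd–Warshall closure."""
    dv = to_distance(graph, map_name)
    nodes = list(graph.nodes)
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    d = np.full((n, n), math.inf)
    np.fill_diagonal(d, 0.0)
    for (u, v), dd in dv.distance.items():
        d[idx[u], idx[v]] = d[idx[v], idx[u]] = dd
    for k in range(n):
        d = np.minimum(d, d[:, [k]] + d[[k], :])
    return {
        e for e, de in dv.distance.items() if _close(de, float(d[idx[e[0]], idx[e[1]]]))
    }


def _all_simple_paths(adj, source, target):
    stack = [(source, [source])]
    while stack:
        u, path = stack.pop()
        if u == target:
            yield path
            continue
        for v in adj[u]:
            if v not in path:
                stack.append((v, path + [v]))


def _adj(graph: WeightedGraph):
    adj = {n: [] for n in graph.nodes}
    for u, v in graph.edge_set:
        adj[u].append(v)
        adj[v].append(u)
    return adj


def minimax_closure(graph: WeightedGraph, map_name: str = "inverse"):
    """Ultrametric backbone edge set via exhaustive simple-path enumeration:
    keep an edge iff its distance ≤ the minimum over all simple paths of the
    maximum edge distance along the path."""
    dv = to_distance(graph, map_name)
    d = dv.distance
    adj = _adj(graph)
    kept = set()
    for (u, v), de in d.items():
        best = math.inf
        for path in _all_simple_paths(adj, u, v):
            mx = max(d[edge_key(a, b)] for a, b in zip(path, path[1:]))
            best = min(best, mx)
        if _close(de, best):
            kept.add((u, v))
    return kept


def brute_salience(graph: WeightedGraph, map_name: str = "inverse"):
    """Edge salience via per-root shortest-path-tree counting.

    Uses the distance condition: edge (u, v) is on a shortest path from root
    r iff dist(r, u) + d_uv == dist(r, v) (either orientation), with dist
    from a Floyd–Warshall closure — no Dijkstra predecessor machinery.
    """
    dv = to_distance(graph, map_name)
    nodes = list(graph.nodes)
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    d = np.full((n, n), math.inf)
    np.fill_diagonal(d, 0.0)
    for (u, v), dd in dv.distance.items():
        d[idx[u], idx[v]] = d[idx[v], idx[u]] = dd
    for k in range(n):
        d = np.minimum(d, d[:, [k]] + d[[k], :])
    counts = {e: 0 for e in dv.distance}
    for r in nodes:
        ri = idx[r]
        for (u, v), duv in dv.distance.items():
            ui, vi = idx[u], idx[v]
            if math.isinf(d[ri, ui]) and math.isinf(d[ri, vi]):
                continue
            on = _close(d[ri, ui] + duv, d[ri, vi]) or _close(d[ri, vi] + duv, d[ri, ui])
            if on:
                counts[(u, v)] += 1
    return {e: c / n for e, c in counts.items()}


def brute_edge_betweenness(graph: WeightedGraph, map_name: str | None = None):
    """Raw edge betweenness by enumerating every simple path per node pair.

    For each unordered pair, the shortest paths (by hop count, or by distance
    sum on ``map_name``) share credit equally.  Exponential — tiny graphs only.
    """
    adj = _adj(graph)
    if map_name is None:
        cost = {e: 1.0 for e in graph.edge_set}
    else:
        cost = to_distance(graph, map_name).distance
    bet = {e: 0.0 for e in graph.edge_set}
    nodes = list(graph.nodes)
    for s, t in itertools.combinations(nodes, 2):
        paths = list(_all_simple_paths(adj, s, t))
        if not paths:
            continue
        lengths = [
            sum(cost[edge_key(a, b)] for a, b in zip(p, p[1:])) for p in paths
        ]
        best = min(lengths)
        shortest = [p for p, l in zip(paths, lengths) if _close(l, best)]
        credit = 1.0 / len(shortest)
        for p in shortest:
            for a, b in zip(p, p[1:]):
                bet[edge_key(a, b)] += credit
    return bet


def brute_sinkhorn(graph: WeightedGraph, tol: float = 1e-10, max_iter: int = 50000):
    """Free-standing Sinkhorn balancing with explicit python loops.

    Returns ``(scores, converged)``; scores are the symmetrized normalized
    weights, defined over non-isolated nodes.
    """
    active = sorted({n for e in graph.edge_set for n in e})
    idx = {n: i for i, n in enumerate(active)}
    n = len(active)
    a = [[0.0] * n for _ in range(n)]
    for (u, v), wt in graph.edges.items():
        a[idx[u]][idx[v]] = wt
        a[idx[v]][idx[u]] = wt
    converged = False
    for _ in range(max_iter):
        for i in range(n):
            rs = sum(a[i])
            for j in range(n):
                a[i][j] /= rs
        for j in range(n):
            cs = sum(a[i][j] for i in range(n))
            for i in range(n):
                a[i][j] /= cs
        resid = 0.0
        for i in range(n):
            resid = max(resid, abs(sum(a[i]) - 1.0))
            resid = max(resid, abs(sum(a[k][i] for k in range(n)) - 1.0))
        if resid < tol:
            converged = True
            break
    scores = {
        e: 0.5 * (a[idx[e[0]]][idx[e[1]]] + a[idx[e[1]]][idx[e[0]]])
        for e in graph.edge_set
    }
    return scores, converged


def brute_ds_backbone(graph: WeightedGraph):
    """Doubly stochastic backbone by the free-standing Sinkhorn loop plus a
    literal add-until-connectivity trace.  Returns None when infeasible."""
    scores, converged = brute_sinkhorn(graph)
    if not converged:
        return None
    target = len(_components(graph.nodes, graph.edge_set))
    kept: set = set()
    for e in sorted(scores, key=lambda e: (-scores[e], e)):
        kept.add(e)
        if len(_components(graph.nodes, kept)) == target:
            break
    return kept


# -- planarity: Kuratowski subdivision search ---------------------------------


def _disjoint_paths_exist(adj, pairs, branch, used, memo_depth=0):
    """Backtracking search for internally-vertex-disjoint paths realizing all
    ``pairs`` between branch vertices, avoiding ``used`` interior vertices."""
    if not pairs:
        return True
    (s, t), rest = pairs[0], pairs[1:]
    # enumerate simple s-t paths whose interior avoids branch and used vertices
    stack = [(s, [s])]
    while stack:
        u, path = stack.pop()
        if u == t:
            interior = set(path[1:-1])
            if _disjoint_paths_exist(adj, rest, branch, used | interior):
                return True
            continue
        for v in adj[u]:
            if v == t and u == s and len(path) == 1:
                # direct edge
                if _disjoint_paths_exist(adj, rest, branch, used):
                    return True
                continue
            if v in path or v in used or (v in branch and v != t):
                continue
            stack.append((v, path + [v]))
    return False


def contains_kuratowski_subdivision(graph) -> bool:
    """True iff the graph contains a subdivision of K5 or K3,3.

    By Kuratowski's theorem this is equivalent to non-planarity.  Exhaustive
    over branch-vertex choices with backtracking disjoint-path search; use
    only for small graphs (n ≤ ~11).
    """
    if isinstance(graph, dict):
        adj = {n: sorted(graph[n]) for n in graph}
    elif isinstance(graph, WeightedGraph):
        adj = {n: sorted(graph.neighbors(n)) for n in graph.nodes}
    else:  # networkx graph
        adj = {n: sorted(graph.neighbors(n)) for n in graph.nodes()}
    nodes = sorted(adj)
    m = sum(len(v) for v in adj.values()) // 2
    n = len(nodes)
    if n >= 3 and m > 3 * n - 6:
        return True  # Euler bound: certainly nonplanar
    cand = [v for v in nodes if len(adj[v]) >= 3]
    # K5 subdivision: 5 branch vertices of degree >= 4
    for branch in itertools.combinations([v for v in cand if len(adj[v]) >= 4], 5):
        pairs = list(itertools.combinations(branch, 2))
        if _disjoint_paths_exist(adj, pairs, set(branch), set()):
            return True
    # K3,3 subdivision: 3 + 3 branch vertices of degree >= 3
    for six in itertools.combinations(cand, 6):
        for left in itertools.combinations(six, 3):
            if six[0] not in left:
                continue  # fix first vertex on the left to halve the work
            right = tuple(v for v in six if v not in left)
            pairs = [(a, b) for a in left for b in right]
            if _disjoint_paths_exist(adj, pairs, set(six), set()):
                return True
    return False


def brute_planar(graph) -> bool:
    return not contains_kuratowski_subdivision(graph)


def pmfg_oracle(graph: WeightedGraph):
    """Greedy planar filter re-traced with the Kuratowski planarity oracle."""
    w = graph.edges
    kept: set = set()
    adj: dict[str, set] = {n: set() for n in graph.nodes}
    for e in sorted(w, key=lambda e: (-w[e], e)):
        u, v = e
        adj[u].add(v)
        adj[v].add(u)
        if brute_planar(adj):
            kept.add(e)
        else:
            adj[u].discard(v)
            adj[v].discard(u)
    return kept


def _h_index_brute(values) -> int:
    """Largest h with at least h values >= h, by testing every candidate."""
    vals = list(values)
    h = 0
    for cand in range(1, len(vals) + 1):
        if sum(1 for v in vals if v >= cand) >= cand:
            h = cand
    return h


def oracle_backbones(graph: WeightedGraph, hss_threshold: float = 0.9,
                     map_name: str = "inverse"):
    """All eight backbone edge sets re-derived with the brute-force oracles.

    Used to freeze golden fixtures; every piece is exhaustive (subset
    enumeration, Floyd–Warshall, simple-path enumeration, Kuratowski search,
    free-standing Sinkhorn), so only tiny graphs are tractable.  The DS entry
    is None when balancing is infeasible.
    """
    w = graph.edges
    out = {}
    out["msp"], _ = brute_max_spanning_forest(graph)
    out["pmfg"] = pmfg_oracle(graph)
    plam: set = set()
    for node in graph.nodes:
        incident = sorted(
            (e for e in w if node in e), key=lambda e: (-w[e], e)
        )
        if incident:
            plam.add(incident[0])
    out["plam"] = plam
    h_s = _h_index_brute(w.values())
    strength = {e for e, wt in w.items() if wt >= h_s} if h_s >= 1 else set()
    bridge_val = {
        e: b / graph.n_nodes
        for e, b in brute_edge_betweenness(graph, map_name).items()
    }
    h_b = _h_index_brute(bridge_val.values())
    bridge = {e for e, b in bridge_val.items() if b >= h_b} if h_b >= 1 else set()
    out["hb"] = strength | bridge
    out["mb"] = floyd_warshall_closure(graph, map_name)
    out["umb"] = minimax_closure(graph, map_name)
    out["ds"] = brute_ds_backbone(graph)
    sal = brute_salience(graph, map_name)
    out["hss"] = {e for e, s in sal.items() if s >= hss_threshold}
    return out


def brute_ks(sample_a, sample_b) -> float:
    """Two-sample KS by double-loop ECDF evaluation at every sample point."""
    a = sorted(float(x) for x in sample_a)
    b = sorted(float(x) for x in sample_b)
    pts = a + b
    best = 0.0
    for x in pts:
        fa = sum(1 for v in a if v <= x) / len(a)
        fb = sum(1 for v in b if v <= x) / len(b)
        best = max(best, abs(fa - fb))
    return best
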