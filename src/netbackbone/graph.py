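"""Weighted-graph data model, edge-list / GraphML I/O, and weight→distance maps.

A :class:`WeightedGraph` is an undirected simple graph with strictly positive,
finite edge weights ``w_ij`` (dimensionless interaction strengths).  It is the
universal input of every backbone extractor.  Node labels are opaque strings;
every deterministic ordering in the package uses lexicographic label order so
that results are reproducible regardless of insertion order.

Distance-based extractors (metric / ultrametric backbones, the high-salience
skeleton, weighted betweenness) operate on a :class:`DistanceView`, obtained by
applying a strictly decreasing weight→distance map — stronger ties are closer.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx

__all__ = [
    "WeightedGraph",
    "DistanceView",
    "Backbone",
    "GraphValidationError",
    "EdgeListParseError",
    "edge_key",
    "read_edge_list",
    "write_edge_list",
    "read_graphml",
    "write_graphml",
    "to_distance",
    "DISTANCE_MAPS",
]

DISTANCE_MAPS = ("inverse", "inverse_minus_one", "max_minus")

METHODS = ("msp", "pmfg", "plam", "hb", "mb", "umb", "ds", "hss")


class GraphValidationError(ValueError):
    """An input violates the weighted-graph invariants."""


class EdgeListParseError(ValueError):
    """A malformed row in an edge-list file."""


def edge_key(u: str, v: str) -> tuple[str, str]:
    """Canonical unordered edge key: labels sorted lexicographically."""
    return (u, v) if u <= v else (v, u)


class WeightedGraph:
    """Undirected simple graph with positive edge weights.

    Parameters
    ----------
    edges : mapping ``(u, v) -> weight`` or iterable of ``(u, v, weight)``
        Edge weights; node labels are coerced to ``str``.
    nodes : iterable of labels, optional
        Extra (possibly isolated) nodes beyond the edge endpoints.

    Raises
    ------
    GraphValidationError
        On self-loops, duplicate edges, non-positive or non-finite weights,
        or an empty node set.
    """

    __slots__ = ("_nodes", "_w", "_nx_cache")

    def __init__(self, edges=None, nodes: Iterable | None = None):
        w: dict[tuple[str, str], float] = {}
        node_set: set[str] = set(str(n) for n in (nodes or ()))
        items: Iterable
        if edges is None:
            items = ()
        elif isinstance(edges, Mapping):
            items = ((u, v, wt) for (u, v), wt in edges.items())
        else:
            items = edges
        for u, v, wt in items:
            u, v = str(u), str(v)
            if u == v:
                raise GraphValidationError(f"self-loop on node {u!r}")
            wt = float(wt)
            if not math.isfinite(wt) or wt <= 0:
                raise GraphValidationError(
                    f"edge ({u!r}, {v!r}) has non-positive or non-finite weight {wt!r}"
                )
            k = edge_key(u, v)
            if k in w:
                raise GraphValidationError(f"duplicate edge {k!r}")
            w[k] = wt
            node_set.add(u)
            node_set.add(v)
        if not node_set:
            raise GraphValidationError("graph must have at least one node")
        self._nodes: tuple[str, ...] = tuple(sorted(node_set))
        self._w = w
        self._nx_cache: nx.Graph | None = None

    # -- construction helpers -------------------------------------------------

    @classmethod
    def from_nx(cls, g: nx.Graph, weight: str = "weight") -> "WeightedGraph":
        """Build from a :class:`networkx.Graph`; missing weights default to 1."""
        if g.is_directed() or g.is_multigraph():
            raise GraphValidationError("only undirected simple graphs are supported")
        edges = [(u, v, d.get(weight, 1.0)) for u, v, d in g.edges(data=True) if u != v]
        return cls(edges, nodes=g.nodes())

    # -- basic accessors ------------------------------------------------------

    @property
    def nodes(self) -> tuple[str, ...]:
        return self._nodes

    @property
    def edges(self) -> dict[tuple[str, str], float]:
        """Edge → weight map (a copy; keys are canonical label pairs)."""
        return dict(self._w)

    @property
    def edge_set(self) -> frozenset[tuple[str, str]]:
        return frozenset(self._w)

    @property
    def n_nodes(self) -> int:
        return len(self._nodes)

    @property
    def n_edges(self) -> int:
        return len(self._w)

    def weight(self, u, v) -> float:
        return self._w[edge_key(str(u), str(v))]

    def has_edge(self, u, v) -> bool:
        return edge_key(str(u), str(v)) in self._w

    def total_weight(self) -> float:
        return sum(self._w.values())

    def density(self) -> float:
        n = self.n_nodes
        return 0.0 if n < 2 else 2.0 * self.n_edges / (n * (n - 1))

    def degrees(self) -> dict[str, int]:
        d = {n: 0 for n in self._nodes}
        for u, v in self._w:
            d[u] += 1
            d[v] += 1
        return d

    def strengths(self) -> dict[str, float]:
        """Node strengths s_i = sum of incident edge weights."""
        s = {n: 0.0 for n in self._nodes}
        for (u, v), wt in self._w.items():
            s[u] += wt
            s[v] += wt
        return s

    def neighbors(self, u) -> list[str]:
        u = str(u)
        out = []
        for a, b in self._w:
            if a == u:
                out.append(b)
            elif b == u:
                out.append(a)
        return sorted(out)

    def to_nx(self) -> nx.Graph:
        """networkx view with a ``weight`` attribute (cached, do not mutate)."""
        if self._nx_cache is None:
            g = nx.Graph()
            g.add_nodes_from(self._nodes)
            g.add_weighted_edges_from((u, v, w) for (u, v), w in self._w.items())
            self._nx_cache = g
        return self._nx_cache

    def __eq__(self, other) -> bool:
        if not isinstance(other, WeightedGraph):
            return NotImplemented
        return self._nodes == other._nodes and self._w == other._w

    def __hash__(self):
        return hash((self._nodes, frozenset(self._w.items())))

    def __repr__(self) -> str:
        return f"WeightedGraph(n_nodes={self.n_nodes}, n_edges={self.n_edges})"


@dataclass(frozen=True)
class DistanceView:
    """Per-edge distances obtained from a strictly decreasing weight map.

    ``map_name`` is one of :data:`DISTANCE_MAPS`:

    - ``inverse``: ``d = 1/w``;
    - ``inverse_minus_one``: ``d = w_max/w − 1`` (proximity-style; the
      strongest edge gets distance 0);
    - ``max_minus``: ``d = w_max + w_min − w``.

    All three reverse the weight order, so order-only methods (MSP, PLAM,
    UMB) are invariant to the choice; metric sums (MB, HSS, weighted
    betweenness) are not, which is why the map name is carried in provenance.
    """

    parent: WeightedGraph
    distance: dict[tuple[str, str], float]
    map_name: str

    def to_nx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.parent.nodes)
        for (u, v), d in self.distance.items():
            g.add_edge(u, v, distance=d)
        return g


def to_distance(graph: WeightedGraph, map_name: str = "inverse") -> DistanceView:
    """Apply the named weight→distance map to every edge."""
    if map_name not in DISTANCE_MAPS:
        raise ValueError(f"unknown distance map {map_name!r}; choose from {DISTANCE_MAPS}")
    w = graph.edges
    if not w:
        return DistanceView(graph, {}, map_name)
    wmax = max(w.values())
    wmin = min(w.values())
    if map_name == "inverse":
        dist = {e: 1.0 / wt for e, wt in w.items()}
    elif map_name == "inverse_minus_one":
        dist = {e: wmax / wt - 1.0 for e, wt in w.items()}
    else:  # max_minus
        dist = {e: wmax + wmin - wt for e, wt in w.items()}
    return DistanceView(graph, dist, map_name)


@dataclass(frozen=True)
class Backbone:
    """Result of one extraction: the retained edge/node subsets of a parent.

    Weights on kept edges are the parent's weights, unaltered.  ``score``
    optionally carries the per-edge quantity the method thresholds or sorts by
    (doubly-stochastic normalized weight, salience).  ``params`` records the
    provenance needed to reproduce the run (distance map, thresholds, ...).
    """

    method: str
    parent: WeightedGraph
    kept_edges: frozenset[tuple[str, str]]
    kept_nodes: frozenset[str]
    score: dict[tuple[str, str], float] | None = None
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        extra = self.kept_edges - self.parent.edge_set
        if extra:
            raise GraphValidationError(f"kept edges not in parent: {sorted(extra)[:3]}")
        if not self.kept_nodes <= set(self.parent.nodes):
            raise GraphValidationError("kept nodes not in parent")

    @property
    def n_edges(self) -> int:
        return len(self.kept_edges)

    @property
    def n_nodes(self) -> int:
        return len(self.kept_nodes)

    def edge_weights(self) -> dict[tuple[str, str], float]:
        pw = self.parent.edges
        return {e: pw[e] for e in self.kept_edges}

    def to_nx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(sorted(self.kept_nodes))
        pw = self.parent.edges
        g.add_weighted_edges_from((u, v, pw[(u, v)]) for (u, v) in self.kept_edges)
        return g

    def to_graph(self) -> WeightedGraph:
        return WeightedGraph(self.edge_weights(), nodes=self.kept_nodes)

    def provenance(self) -> dict:
        return {
            "method": self.method,
            "n_edges": self.n_edges,
            "n_nodes": self.n_nodes,
            "parent_n_edges": self.parent.n_edges,
            "parent_n_nodes": self.parent.n_nodes,
            "params": dict(self.params),
        }


# -- file formats -------------------------------------------------------------


def _fmt(x: float) -> str:
    """Shortest decimal string that round-trips the float exactly."""
    return repr(float(x))


def read_edge_list(
    path,
    delimiter: str | None = None,
    header: str | bool = "auto",
    dedup_policy: str = "error",
) -> WeightedGraph:
    """Read a ``source,target,weight`` edge list.

    Lines starting with ``#`` are skipped.  ``delimiter=None`` sniffs between
    tab and comma.  ``header`` may be True/False or ``"auto"`` (first line is
    treated as a header when its third field does not parse as a number).
    Duplicate undirected pairs — including reversed ``(v, u)`` rows — are
    resolved per ``dedup_policy`` in {"error", "mean", "sum", "max"}.
    Self-loops are dropped with a warning: the extraction methods are defined
    on simple graphs.
    """
    if dedup_policy not in ("error", "mean", "sum", "max"):
        raise ValueError(f"unknown dedup_policy {dedup_policy!r}")
    rows: list[tuple[str, str, float, int]] = []
    with open(path, "r", encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    first_data = True
    for lineno, line in enumerate(lines, 1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        delim = delimiter
        if delim is None:
            delim = "\t" if "\t" in line else ","
        parts = [p.strip() for p in stripped.split(delim)]
        if len(parts) < 3:
            raise EdgeListParseError(f"line {lineno}: expected 3 columns, got {len(parts)}")
        if first_data:
            first_data = False
            skip = header is True
            if header == "auto":
                try:
                    float(parts[2])
                except ValueError:
                    skip = True
            if skip:
                continue
        try:
            wt = float(parts[2])
        except ValueError as exc:
            raise EdgeListParseError(f"line {lineno}: weight {parts[2]!r} is not a number") from exc
        if not math.isfinite(wt) or wt <= 0:
            raise GraphValidationError(f"line {lineno}: non-positive or non-finite weight {wt!r}")
        rows.append((parts[0], parts[1], wt, lineno))

    agg: dict[tuple[str, str], list[float]] = {}
    dropped_loops = 0
    for u, v, wt, lineno in rows:
        if u == v:
            dropped_loops += 1
            continue
        k = edge_key(u, v)
        if k in agg and dedup_policy == "error":
            raise GraphValidationError(f"line {lineno}: duplicate undirected pair {k!r}")
        agg.setdefault(k, []).append(wt)
    if dropped_loops:
        warnings.warn(f"dropped {dropped_loops} self-loop row(s)", stacklevel=2)
    reduce = {"error": lambda v: v[0], "mean": lambda v: sum(v) / len(v),
              "sum": sum, "max": max}[dedup_policy]
    return WeightedGraph({k: reduce(v) for k, v in agg.items()})


def write_edge_list(obj, path, include_score: bool = False) -> None:
    """Write a graph or backbone as a sorted CSV edge list.

    Rows are sorted by ``(min label, max label)`` for byte-stable output;
    weights use shortest round-tripping decimal strings so that
    ``read(write(g)) == g`` exactly.
    """
    if isinstance(obj, Backbone):
        weights = obj.edge_weights()
        score = obj.score if include_score else None
    elif isinstance(obj, WeightedGraph):
        weights = obj.edges
        score = None
        if include_score:
            raise ValueError("include_score applies to Backbone outputs only")
    else:
        raise TypeError(f"expected WeightedGraph or Backbone, got {type(obj).__name__}")
    cols = "source,target,weight" + (",score" if score is not None else "")
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(cols + "\n")
        for u, v in sorted(weights):
            row = f"{u},{v},{_fmt(weights[(u, v)])}"
            if score is not None:
                row += f",{_fmt(score.get((u, v), float('nan')))}"
            fh.write(row + "\n")


def write_provenance(backbone: Backbone, path) -> None:
    """JSON sidecar recording method, parameters and counts."""
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(backbone.provenance(), fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_graphml(path, weight: str = "weight") -> WeightedGraph:
    return WeightedGraph.from_nx(nx.read_graphml(path), weight=weight)


def write_graphml(obj, path) -> None:
    g = obj.to_nx() if isinstance(obj, (WeightedGraph, Backbone)) else obj
    nx.write_graphml(g, path)
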