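"""Evaluation metrics for comparing backbones.

Four families of computations:

* pairwise similarity between backbones — Jaccard index and the asymmetric
  overlap coefficients — with mean / population-std aggregation across
  networks;
* point-biserial correlation between edge membership (0/1) and per-edge
  properties of the original graph (weight, degree product, strength product,
  betweenness, weighted betweenness);
* global topological properties of a backbone, normalized by the original
  network's value;
* two-sample Kolmogorov–Smirnov statistics between backbone and original
  weight / degree distributions, with average-rank method ranking.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .graph import Backbone, WeightedGraph, edge_key, to_distance

__all__ = [
    "PairSimilarity",
    "AggregateStats",
    "GlobalPropertyReport",
    "pair_similarity",
    "aggregate",
    "edge_properties",
    "EDGE_PROPERTIES",
    "point_biserial",
    "global_properties",
    "GLOBAL_PROPERTIES",
    "ks_statistic",
    "rank_methods",
]

EDGE_PROPERTIES = (
    "weight",
    "degree_product",
    "strength_product",
    "betweenness",
    "weighted_betweenness",
)

GLOBAL_PROPERTIES = (
    "edge_fraction",
    "node_fraction",
    "weight_fraction",
    "weight_entropy",
    "reachability",
    "n_components",
    "transitivity",
)


# -- similarity ---------------------------------------------------------------


@dataclass(frozen=True)
class PairSimilarity:
    """Jaccard and asymmetric overlap coefficients of two edge sets.

    ``overlap_from_first`` = |E1 ∩ E2| / |E1| equals 1 iff E1 ⊆ E2.
    Both-empty sets compare as identical (J = Ov = 1 by convention).
    """

    jaccard: float
    overlap_from_first: float
    overlap_from_second: float


def pair_similarity(b1: Backbone, b2: Backbone) -> PairSimilarity:
    """Exact set arithmetic on the kept edges of two backbones of one parent."""
    if not (b1.parent is b2.parent or b1.parent == b2.parent):
        raise ValueError("backbones come from different parent graphs")
    e1, e2 = b1.kept_edges, b2.kept_edges
    inter = len(e1 & e2)
    union = len(e1 | e2)
    j = 1.0 if union == 0 else inter / union
    ov1 = 1.0 if not e1 else inter / len(e1)
    ov2 = 1.0 if not e2 else inter / len(e2)
    return PairSimilarity(j, ov1, ov2)


@dataclass(frozen=True)
class AggregateStats:
    """Mean and population standard deviation (denominator N) of per-network
    similarity values."""

    mean: float
    std: float
    n: int


def aggregate(values) -> AggregateStats:
    vals = np.asarray(list(values), dtype=float)
    if vals.size == 0:
        raise ValueError("aggregate requires a nonempty list")
    return AggregateStats(float(vals.mean()), float(vals.std(ddof=0)), int(vals.size))


# -- per-edge properties ------------------------------------------------------


def edge_properties(graph: WeightedGraph, map_name: str = "inverse") -> pd.DataFrame:
    """Per-edge property table of the original graph.

    One row per edge (index = canonical label pair), columns
    :data:`EDGE_PROPERTIES`.  Betweenness is the raw shortest-path pair count
    through the edge with fractional credit for tied paths; the weighted
    variant routes paths by distance sum on the chosen map.
    """
    w = graph.edges
    deg = graph.degrees()
    stren = graph.strengths()
    eb = nx.edge_betweenness_centrality(graph.to_nx(), normalized=False)
    eb = {edge_key(*e): b for e, b in eb.items()}
    gw = to_distance(graph, map_name).to_nx()
    ebw = nx.edge_betweenness_centrality(gw, normalized=False, weight="distance")
    ebw = {edge_key(*e): b for e, b in ebw.items()}
    edges = sorted(w)
    return pd.DataFrame(
        {
            "weight": [w[e] for e in edges],
            "degree_product": [deg[u] * deg[v] for u, v in edges],
            "strength_product": [stren[u] * stren[v] for u, v in edges],
            "betweenness": [eb[e] for e in edges],
            "weighted_betweenness": [ebw[e] for e in edges],
        },
        index=pd.MultiIndex.from_tuples(edges, names=["source", "target"]),
    )


def point_biserial(presence, values) -> float:
    """Point-biserial correlation between a 0/1 membership vector and values.

    r_pb = (M1 − M0) / s_n · sqrt(n1·n0 / n²) with the population standard
    deviation s_n; algebraically identical to the Pearson correlation of the
    dichotomous coding with the values.  Returns NaN when undefined (one
    group empty, or zero variance in ``values``).
    """
    p = np.asarray(presence, dtype=float)
    y = np.asarray(values, dtype=float)
    if p.shape != y.shape or p.ndim != 1 or p.size < 2:
        raise ValueError("presence and values must be equal-length 1-d arrays, n >= 2")
    if not np.isin(p, (0.0, 1.0)).all():
        raise ValueError("presence must be 0/1 coded")
    n = p.size
    n1 = int(p.sum())
    n0 = n - n1
    if n1 == 0 or n0 == 0:
        return float("nan")
    s = y.std(ddof=0)
    if s == 0:
        return float("nan")
    m1 = y[p == 1].mean()
    m0 = y[p == 0].mean()
    return float((m1 - m0) / s * math.sqrt(n1 * n0 / n**2))


# -- global properties --------------------------------------------------------


def _weight_entropy(weights, mode: str = "proportion", bins: int = 20) -> float:
    """Shannon entropy (natural log) of edge weights.

    ``proportion`` (default): entropy of p_e = w_e / Σw over the edge set.
    ``histogram``: entropy of a fixed-bin weight histogram — an alternative
    reading kept behind a flag for sensitivity checks.
    """
    w = np.asarray(list(weights), dtype=float)
    if w.size == 0:
        return 0.0
    if mode == "proportion":
        p = w / w.sum()
    elif mode == "histogram":
        counts, _ = np.histogram(w, bins=bins)
        counts = counts[counts > 0]
        p = counts / counts.sum()
    else:
        raise ValueError(f"unknown entropy mode {mode!r}")
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def _reachability(g: nx.Graph, denominator_nodes: int) -> float:
    """Connected unordered node pairs over C(denominator_nodes, 2); nodes
    absent from ``g`` count as unreachable."""
    total = denominator_nodes * (denominator_nodes - 1) / 2
    if total == 0:
        return float("nan")
    pairs = sum(
        len(c) * (len(c) - 1) / 2 for c in nx.connected_components(g)
    )
    return pairs / total


@dataclass(frozen=True)
class GlobalPropertyReport:
    """Raw and original-normalized global properties of one backbone.

    ``normalized[p] = raw[p] / original[p]``; reported as NaN where the
    original value is 0 (undefined ratio).  ``n_components`` is raw only —
    a count, not a fraction.
    """

    method: str
    raw: dict
    original: dict
    normalized: dict

    def as_series(self) -> pd.Series:
        data = {}
        for p in GLOBAL_PROPERTIES:
            data[(p, "raw")] = self.raw[p]
            data[(p, "normalized")] = self.normalized.get(p, float("nan"))
        return pd.Series(data)


def global_properties(
    backbone: Backbone, entropy_mode: str = "proportion"
) -> GlobalPropertyReport:
    """The seven global properties of a backbone, raw and normalized.

    edge / node / weight fractions are relative to the original; weight
    entropy is the Shannon entropy of the weight proportions; reachability
    uses the ORIGINAL node count in its denominator so node-dropping methods
    are penalized; components are counted over kept nodes only; transitivity
    is 3·triangles / connected triples.
    """
    parent = backbone.parent
    bg = backbone.to_nx()
    og = parent.to_nx()
    n_o, m_o = parent.n_nodes, parent.n_edges
    kept_w = backbone.edge_weights()

    raw = {
        "edge_fraction": len(backbone.kept_edges) / m_o if m_o else float("nan"),
        "node_fraction": len(backbone.kept_nodes) / n_o,
        "weight_fraction": (
            sum(kept_w.values()) / parent.total_weight() if m_o else float("nan")
        ),
        "weight_entropy": _weight_entropy(kept_w.values(), entropy_mode),
        "reachability": _reachability(bg, n_o),
        "n_components": (
            nx.number_connected_components(bg) if backbone.kept_nodes else 0
        ),
        "transitivity": nx.transitivity(bg) if backbone.kept_nodes else 0.0,
    }
    original = {
        "edge_fraction": 1.0 if m_o else float("nan"),
        "node_fraction": 1.0,
        "weight_fraction": 1.0 if m_o else float("nan"),
        "weight_entropy": _weight_entropy(parent.edges.values(), entropy_mode),
        "reachability": _reachability(og, n_o),
        "n_components": nx.number_connected_components(og),
        "transitivity": nx.transitivity(og),
    }
    normalized = {}
    for p in GLOBAL_PROPERTIES:
        if p == "n_components":
            continue  # reported raw; a count on a log scale, not a ratio
        o = float(original[p])
        r = float(raw[p])
        if math.isnan(o) or o == 0.0:
            normalized[p] = float("nan")
        else:
            normalized[p] = r / o
    return GlobalPropertyReport(backbone.method, raw, original, normalized)


# -- distribution comparison --------------------------------------------------


def ks_statistic(sample_a, sample_b) -> float:
    """Two-sample Kolmogorov–Smirnov statistic: sup |ECDF_a − ECDF_b|."""
    a = np.asarray(list(sample_a), dtype=float)
    b = np.asarray(list(sample_b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("ks_statistic requires two nonempty samples")
    return float(stats.ks_2samp(a, b, method="asymp").statistic)


def rank_methods(ks_by_method: dict) -> dict:
    """Ascending ranks on KS values (1 = closest to the original);
    ties receive the average of their positional ranks."""
    if len(ks_by_method) < 2:
        raise ValueError("rank_methods requires at least two methods")
    methods = sorted(ks_by_method)
    ranks = stats.rankdata([ks_by_method[m] for m in methods], method="average")
    return {m: float(r) for m, r in zip(methods, ranks)}
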