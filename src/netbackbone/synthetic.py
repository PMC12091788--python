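"""Seeded synthetic weighted networks.

A real-world benchmark corpus for backbone extraction spans character, social,
biological and infrastructural networks whose densities range over roughly
0.01–0.9, clustering over 0–0.9 and sizes over 10–5,000 nodes, with
heterogeneous positive edge weights (contact counts, traffic volumes,
correlation strengths).  This module emulates that diversity with four
topology families (Erdős–Rényi, Barabási–Albert, Watts–Strogatz, stochastic
block model) crossed with four weight laws (uniform, log-normal, Pareto,
constant), plus tiny deterministic fixtures whose backbones are pre-computed
by the brute-force oracles.

Determinism: a panel seed spawns per-graph seeds through
``numpy.random.SeedSequence([panel_seed, index])``, so adding a graph to a
panel never perturbs earlier ones, and the same spec + seed reproduces the
same graph byte-for-byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .graph import WeightedGraph

__all__ = [
    "WeightLaw",
    "SyntheticSpec",
    "generate",
    "corpus_panel",
    "panel_recipes",
    "fixtures",
]

FAMILIES = ("random_uniform", "preferential_attachment", "small_world", "block_model")
WEIGHT_LAWS = ("uniform", "lognormal", "pareto", "constant")


@dataclass(frozen=True)
class WeightLaw:
    """Edge-weight distribution: one of ``uniform(a, b)``, ``lognormal(mu,
    sigma)``, ``pareto(alpha, x_min)``, ``constant(c)``."""

    name: str
    params: tuple = ()

    def __post_init__(self):
        if self.name not in WEIGHT_LAWS:
            raise ValueError(f"unknown weight law {self.name!r}")

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.name == "uniform":
            a, b = self.params
            return rng.uniform(a, b, size)
        if self.name == "lognormal":
            mu, sigma = self.params
            return rng.lognormal(mu, sigma, size)
        if self.name == "pareto":
            alpha, xmin = self.params
            return xmin * (1.0 + rng.pareto(alpha, size))
        c = self.params[0]
        return np.full(size, float(c))

    def label(self) -> str:
        return f"{self.name}({', '.join(repr(p) for p in self.params)})"


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one synthetic weighted network.

    ``params`` by family: random_uniform → ``p``; preferential_attachment →
    ``m``; small_world → ``k``, ``beta``; block_model → ``sizes`` (list),
    ``p_in``, ``p_out``.  ``distinct_weights`` applies a deterministic
    rank-based jitter so that no two edges share a weight.
    """

    family: str
    n_nodes: int
    params: dict = field(default_factory=dict)
    weight_law: WeightLaw = WeightLaw("uniform", (1.0, 10.0))
    distinct_weights: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.n_nodes < 1:
            raise ValueError("n_nodes must be >= 1")
        p = self.params
        if self.family == "random_uniform" and not 0 <= p.get("p", 0) <= 1:
            raise ValueError("edge probability p must lie in [0, 1]")
        if self.family == "small_world" and not 0 <= p.get("beta", 0) <= 1:
            raise ValueError("rewiring probability beta must lie in [0, 1]")
        if self.family == "block_model":
            if sum(p.get("sizes", [])) != self.n_nodes:
                raise ValueError("block sizes must sum to n_nodes")
            for q in (p.get("p_in", 0), p.get("p_out", 0)):
                if not 0 <= q <= 1:
                    raise ValueError("block probabilities must lie in [0, 1]")


def _derived_seed(*entropy) -> int:
    """Deterministic child seed below 2**31."""
    return int(np.random.SeedSequence(list(entropy)).generate_state(1)[0] % (2**31))


def _topology(spec: SyntheticSpec) -> nx.Graph:
    seed = _derived_seed(spec.seed, 1)
    n, p = spec.n_nodes, spec.params
    if spec.family == "random_uniform":
        return nx.gnp_random_graph(n, p["p"], seed=seed)
    if spec.family == "preferential_attachment":
        return nx.barabasi_albert_graph(n, p["m"], seed=seed)
    if spec.family == "small_world":
        return nx.watts_strogatz_graph(n, p["k"], p["beta"], seed=seed)
    probs_sizes = p["sizes"]
    k = len(probs_sizes)
    mat = [[p["p_in"] if i == j else p["p_out"] for j in range(k)] for i in range(k)]
    return nx.stochastic_block_model(probs_sizes, mat, seed=seed)


def _make_distinct(weights: np.ndarray) -> np.ndarray:
    """Deterministic rank-based jitter enforcing all-distinct positive weights."""
    w = weights.astype(float).copy()
    m = w.size
    if m <= 1 or np.unique(w).size == m:
        return w
    order = np.argsort(w, kind="stable")
    delta = max(float(w.mean()) * 1e-9 / max(m, 1), 1e-12)
    for _ in range(60):
        jittered = w.copy()
        jittered[order] = w[order] + delta * np.arange(m)
        if np.unique(jittered).size == m:
            return jittered
        delta *= 2.0
    raise RuntimeError("could not enforce distinct weights")


def generate(spec: SyntheticSpec) -> WeightedGraph:
    """Generate the weighted network described by ``spec`` (deterministic)."""
    g = _topology(spec)
    width = max(4, len(str(spec.n_nodes - 1)))
    label = {i: f"n{i:0{width}d}" for i in g.nodes()}
    edges = sorted((min(label[u], label[v]), max(label[u], label[v])) for u, v in g.edges())
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 2]))
    w = spec.weight_law.sample(rng, len(edges))
    if spec.distinct_weights:
        w = _make_distinct(w)
    assert (w > 0).all()
    return WeightedGraph(
        {e: float(wt) for e, wt in zip(edges, w)},
        nodes=label.values(),
    )


# -- default corpus panel -----------------------------------------------------

_U = lambda a, b: WeightLaw("uniform", (float(a), float(b)))
_L = lambda mu, s: WeightLaw("lognormal", (float(mu), float(s)))
_P = lambda a, x: WeightLaw("pareto", (float(a), float(x)))

# (name, family, n, params, weight law).  Chosen to span density ~0.02–0.9 and
# clustering ~0–0.9 with mixed weight laws; average degree is kept >= ~8 on
# nearly every graph (as in real corpora, where even sparse networks have
# many more edges than nodes), and the largest graphs are the sparsest so the
# full pipeline stays desk-scale.  Five graphs exceed 1000 edges and thus
# enter the distribution-comparison experiment at its default cutoff.
_PANEL = [
    ("dense_gnp_10", "random_uniform", 10, {"p": 0.9}, _U(1, 10)),
    ("dense_gnp_12", "random_uniform", 12, {"p": 0.85}, _L(1.0, 0.8)),
    ("dense_gnp_15", "random_uniform", 15, {"p": 0.8}, _U(1, 10)),
    ("gnp_20_half", "random_uniform", 20, {"p": 0.5}, _U(1, 10)),
    ("gnp_30_mid", "random_uniform", 30, {"p": 0.35}, _P(2.0, 1.0)),
    ("gnp_40_mid", "random_uniform", 40, {"p": 0.3}, _L(0.0, 1.0)),
    ("gnp_60_dense", "random_uniform", 60, {"p": 0.6}, _U(1, 100)),
    ("gnp_80_sparse", "random_uniform", 80, {"p": 0.15}, _U(1, 10)),
    ("gnp_120_sparse", "random_uniform", 120, {"p": 0.1}, _L(0.0, 1.0)),
    ("gnp_200_sparse", "random_uniform", 200, {"p": 0.06}, _P(1.5, 1.0)),
    ("gnp_500_sparse", "random_uniform", 500, {"p": 0.02}, _U(1, 10)),
    ("pa_50", "preferential_attachment", 50, {"m": 5}, _U(1, 10)),
    ("pa_100", "preferential_attachment", 100, {"m": 5}, _L(0.0, 1.0)),
    ("pa_200", "preferential_attachment", 200, {"m": 6}, _P(2.0, 1.0)),
    ("pa_400", "preferential_attachment", 400, {"m": 5}, _U(1, 50)),
    ("ws_30", "small_world", 30, {"k": 8, "beta": 0.05}, _U(1, 10)),
    ("ws_60", "small_world", 60, {"k": 10, "beta": 0.1}, _L(0.0, 1.0)),
    ("ws_100_lattice", "small_world", 100, {"k": 8, "beta": 0.0}, _U(1, 10)),
    ("ws_150", "small_world", 150, {"k": 10, "beta": 0.2}, _P(2.0, 1.0)),
    ("ws_250", "small_world", 250, {"k": 8, "beta": 0.3}, _U(1, 10)),
    ("ws_40_clustered", "small_world", 40, {"k": 12, "beta": 0.02}, _U(5, 50)),
    ("sbm_40", "block_model", 40, {"sizes": [20, 20], "p_in": 0.5, "p_out": 0.1}, _U(1, 10)),
    ("sbm_90", "block_model", 90, {"sizes": [30, 30, 30], "p_in": 0.4, "p_out": 0.05}, _L(0.0, 1.0)),
    ("sbm_150", "block_model", 150, {"sizes": [75, 75], "p_in": 0.2, "p_out": 0.04}, _P(2.0, 1.0)),
]


def panel_recipes(seed: int = 0) -> list[SyntheticSpec]:
    """The default panel's specs, with per-graph seeds derived from ``seed``."""
    return [
        SyntheticSpec(family, n, params, law, distinct_weights=True,
                      seed=_derived_seed(seed, i))
        for i, (_, family, n, params, law) in enumerate(_PANEL)
    ]


def corpus_panel(seed: int = 0):
    """Generate the default 24-graph panel.

    Returns ``(graphs, manifest)``: an ordered ``{name: WeightedGraph}`` and a
    DataFrame with the realized per-graph density, clustering and size.
    """
    graphs: dict[str, WeightedGraph] = {}
    rows = []
    for spec, (name, family, n, params, law) in zip(panel_recipes(seed), _PANEL):
        g = generate(spec)
        graphs[name] = g
        rows.append(
            {
                "name": name,
                "family": family,
                "n_nodes": g.n_nodes,
                "n_edges": g.n_edges,
                "density": g.density(),
                "avg_clustering": nx.average_clustering(g.to_nx()),
                "weight_law": law.label(),
                "seed": spec.seed,
            }
        )
    return graphs, pd.DataFrame(rows)


# -- deterministic fixtures ---------------------------------------------------


def fixtures() -> dict[str, WeightedGraph]:
    """Small, fully deterministic graphs used throughout the test suite.

    ``golden10`` is a 10-node connected graph with all-distinct weights whose
    eight backbones are small enough to re-derive with every brute-force
    oracle; its golden extractions are stored alongside the tests.
    """
    out = {
        "triangle_321": WeightedGraph({("a", "b"): 3, ("b", "c"): 2, ("a", "c"): 1}),
        "path_abc_unit": WeightedGraph({("a", "b"): 1, ("b", "c"): 1}),
        "two_triangles": WeightedGraph(
            {("a", "b"): 3, ("b", "c"): 2, ("a", "c"): 1,
             ("x", "y"): 6, ("y", "z"): 5, ("x", "z"): 4}
        ),
    }
    rng = np.random.default_rng(np.random.SeedSequence([424243, 5]))
    k5_nodes = ["a", "b", "c", "d", "e"]
    k5_edges = [(u, v) for i, u in enumerate(k5_nodes) for v in k5_nodes[i + 1:]]
    k5_w = _make_distinct(rng.uniform(1, 10, len(k5_edges)))
    out["k5_distinct"] = WeightedGraph({e: w for e, w in zip(k5_edges, k5_w)})
    star_edges = [("hub", f"leaf{i}") for i in range(1, 6)]
    out["star6_distinct"] = WeightedGraph(
        {e: float(w) for e, w in zip(star_edges, [5.0, 4.0, 3.0, 2.0, 1.0])}
    )
    out["golden10"] = generate(
        SyntheticSpec("random_uniform", 10, {"p": 0.45},
                      WeightLaw("uniform", (1.0, 10.0)), True, seed=20240602)
    )
    return out
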