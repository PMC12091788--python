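"""Benchmark pipeline: the four comparative experiments over a set of networks.

Given a collection of weighted networks (a directory of edge lists or the
synthetic panel) and a list of methods, the pipeline

1. extracts every backbone once (Sinkhorn-infeasible networks never abort the
   run — the doubly stochastic filter is excluded pairwise for that network
   and the exclusion enumerated),
2. runs the four experiments — pairwise similarity, edge-property correlation,
   global properties, weight/degree distribution comparison — emitting tidy
   long-format tables, and
3. derives a qualitative behavior matrix (consistent-yes / network-dependent /
   consistent-no per method × property) from the global-property table with
   explicit, configurable thresholds echoed in the output.

All outputs are deterministic: identical config + seed produce byte-identical
CSV files.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from . import __version__
from .extractors import EXTRACTORS, extract
from .graph import Backbone, WeightedGraph, read_edge_list
from .metrics import (
    EDGE_PROPERTIES,
    GLOBAL_PROPERTIES,
    aggregate,
    edge_properties,
    global_properties,
    ks_statistic,
    pair_similarity,
    point_biserial,
    rank_methods,
)
from .synthetic import corpus_panel

__all__ = [
    "BenchConfig",
    "DEFAULT_THRESHOLDS",
    "BEHAVIOR_PROPERTIES",
    "extract_all",
    "run_similarity",
    "run_edge_correlation",
    "run_global_properties",
    "run_distribution_comparison",
    "derive_behavior_matrix",
    "run_bench",
]

log = logging.getLogger("netbackbone.bench")

ALL_METHODS = tuple(EXTRACTORS)

BEHAVIOR_PROPERTIES = (
    "heavy_filtering",
    "node_preservative",
    "entropy_preservative",
    "connectivity_preservative",
    "transitivity_preservative",
)

# Operationalization of the qualitative verdicts: a method is a consistent
# heavy filter when it keeps at most `heavy_edge_fraction` of the edges on at
# least `consistency` of the networks; a property is consistently preserved
# (lost) when its normalized value is >= `preserved` (<= `lost`) on at least
# `consistency` of the networks where it is defined; anything else is
# network-dependent.
DEFAULT_THRESHOLDS = {
    "heavy_edge_fraction": 0.25,
    "preserved": 0.9,
    "lost": 0.1,
    "consistency": 0.9,
}

_BEHAVIOR_SOURCE = {
    "node_preservative": "node_fraction",
    "entropy_preservative": "weight_entropy",
    "connectivity_preservative": "reachability",
    "transitivity_preservative": "transitivity",
}


@dataclass
class BenchConfig:
    """Configuration for one benchmark run.

    ``input_dir`` (directory of ``*.csv``/``*.tsv`` edge lists) and
    ``use_panel`` are mutually exclusive input sources.
    """

    input_dir: str | None = None
    use_panel: bool = True
    methods: tuple = ALL_METHODS
    distance_map: str = "inverse"
    salience_threshold: float = 0.9
    ds_tol: float = 1e-8
    ds_max_iter: int = 10000
    hb_betweenness: str = "weighted"
    min_edges_for_distribution: int = 1000
    entropy_mode: str = "proportion"
    thresholds: dict = field(default_factory=lambda: dict(DEFAULT_THRESHOLDS))
    seed: int = 0
    out_dir: str = "bench_out"

    def __post_init__(self):
        unknown = [m for m in self.methods if m not in EXTRACTORS]
        if unknown:
            raise ValueError(f"unknown methods {unknown}; registry: {sorted(EXTRACTORS)}")
        if not self.methods:
            raise ValueError("methods list must be nonempty")
        if self.min_edges_for_distribution < 0:
            raise ValueError("min_edges_for_distribution must be >= 0")

    def method_params(self, method: str) -> dict:
        if method in ("mb", "umb"):
            return {"map_name": self.distance_map}
        if method == "hss":
            return {"threshold": self.salience_threshold, "map_name": self.distance_map}
        if method == "hb":
            return {"betweenness_variant": self.hb_betweenness, "map_name": self.distance_map}
        if method == "ds":
            return {"tol": self.ds_tol, "max_iter": self.ds_max_iter, "on_failure": "skip"}
        return {}

    def to_dict(self) -> dict:
        return {
            "input_dir": self.input_dir,
            "use_panel": self.use_panel,
            "methods": list(self.methods),
            "distance_map": self.distance_map,
            "salience_threshold": self.salience_threshold,
            "ds_tol": self.ds_tol,
            "ds_max_iter": self.ds_max_iter,
            "hb_betweenness": self.hb_betweenness,
            "min_edges_for_distribution": self.min_edges_for_distribution,
            "entropy_mode": self.entropy_mode,
            "thresholds": dict(self.thresholds),
            "seed": self.seed,
        }

    @classmethod
    def from_yaml(cls, path) -> "BenchConfig":
        import yaml

        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if "methods" in raw:
            raw["methods"] = tuple(raw["methods"])
        return cls(**raw)


def load_networks(config: BenchConfig) -> dict[str, WeightedGraph]:
    """Input networks keyed by name, from the panel or an edge-list directory."""
    if config.input_dir is not None:
        graphs = {}
        for p in sorted(Path(config.input_dir).glob("*")):
            if p.suffix.lower() in (".csv", ".tsv", ".edges", ".txt"):
                graphs[p.stem] = read_edge_list(p)
        if not graphs:
            raise FileNotFoundError(f"no edge lists found in {config.input_dir}")
        return graphs
    graphs, _ = corpus_panel(config.seed)
    return graphs


def extract_all(graphs: dict[str, WeightedGraph], config: BenchConfig):
    """Run every method on every network.

    Returns ``(backbones, failures)`` where ``backbones[(network, method)]``
    maps to a Backbone and ``failures`` lists ``(network, method, reason)``
    for methods excluded on a network (currently: Sinkhorn infeasibility).
    """
    backbones: dict[tuple[str, str], Backbone] = {}
    failures: list[tuple[str, str, str]] = []
    for name, g in graphs.items():
        for method in config.methods:
            t0 = time.perf_counter()
            b = extract(method, g, **config.method_params(method))
            if b.params.get("infeasible"):
                failures.append((name, method, "sinkhorn_infeasible"))
                log.info("%s/%s infeasible (excluded)", name, method)
                continue
            backbones[(name, method)] = b
            log.debug("%s/%s: %d edges in %.2fs", name, method, b.n_edges,
                      time.perf_counter() - t0)
    return backbones, failures


def run_similarity(graphs, backbones, methods):
    """Experiment 1: pairwise Jaccard and asymmetric overlap.

    Returns ``(long, jaccard_mean, jaccard_std, overlap_mean, overlap_std)``.
    The overlap matrices are asymmetric: row = the method whose edge set sits
    in the numerator's denominator, i.e. entry (A, B) is |A ∩ B| / |A|.
    """
    rows = []
    for name in graphs:
        for ma in methods:
            for mb_ in methods:
                if ma >= mb_:
                    continue
                ka, kb = (name, ma), (name, mb_)
                if ka not in backbones or kb not in backbones:
                    continue
                ps = pair_similarity(backbones[ka], backbones[kb])
                rows.append({"network": name, "method_a": ma, "method_b": mb_,
                             "jaccard": ps.jaccard, "ov_a": ps.overlap_from_first,
                             "ov_b": ps.overlap_from_second})
    long = pd.DataFrame(rows, columns=["network", "method_a", "method_b",
                                       "jaccard", "ov_a", "ov_b"])
    ms = sorted(methods)
    jm = pd.DataFrame(np.nan, index=ms, columns=ms)
    js = pd.DataFrame(np.nan, index=ms, columns=ms)
    om = pd.DataFrame(np.nan, index=ms, columns=ms)
    os_ = pd.DataFrame(np.nan, index=ms, columns=ms)
    for m in ms:
        jm.loc[m, m] = 1.0
        js.loc[m, m] = 0.0
        om.loc[m, m] = 1.0
        os_.loc[m, m] = 0.0
    for (a, b), sub in long.groupby(["method_a", "method_b"]):
        ag = aggregate(sub["jaccard"])
        jm.loc[a, b] = jm.loc[b, a] = ag.mean
        js.loc[a, b] = js.loc[b, a] = ag.std
        ova = aggregate(sub["ov_a"])
        ovb = aggregate(sub["ov_b"])
        om.loc[a, b], os_.loc[a, b] = ova.mean, ova.std
        om.loc[b, a], os_.loc[b, a] = ovb.mean, ovb.std
    return long, jm, js, om, os_


def run_edge_correlation(graphs, backbones, methods, distance_map="inverse"):
    """Experiment 2: point-biserial correlation of edge membership vs the five
    edge properties, per network × method.  Undefined correlations are
    reported as NaN with a reason."""
    rows = []
    for name, g in graphs.items():
        table = edge_properties(g, map_name=distance_map)
        edges = list(table.index)
        for method in methods:
            key = (name, method)
            if key not in backbones:
                continue
            kept = backbones[key].kept_edges
            presence = np.array([1.0 if e in kept else 0.0 for e in edges])
            for prop in EDGE_PROPERTIES:
                vals = table[prop].to_numpy()
                if presence.sum() in (0, len(edges)):
                    r, reason = float("nan"), "constant_presence"
                elif np.ptp(vals) == 0:
                    r, reason = float("nan"), "constant_property"
                else:
                    r, reason = point_biserial(presence, vals), ""
                rows.append({"network": name, "method": method, "property": prop,
                             "r_pb": r, "reason": reason})
    return pd.DataFrame(rows, columns=["network", "method", "property", "r_pb", "reason"])


def run_global_properties(graphs, backbones, methods, entropy_mode="proportion"):
    """Experiment 3: the seven global properties, raw and normalized."""
    rows = []
    for name in graphs:
        for method in methods:
            key = (name, method)
            if key not in backbones:
                continue
            rep = global_properties(backbones[key], entropy_mode=entropy_mode)
            for prop in GLOBAL_PROPERTIES:
                rows.append({
                    "network": name, "method": method, "property": prop,
                    "raw": rep.raw[prop],
                    "normalized": rep.normalized.get(prop, float("nan")),
                })
    return pd.DataFrame(rows, columns=["network", "method", "property", "raw", "normalized"])


def run_distribution_comparison(graphs, backbones, methods, min_edges=1000):
    """Experiment 4: KS statistics of backbone weight and degree distributions
    vs the original, and per-network method ranks (1 = closest).

    Networks with fewer than ``min_edges`` edges are excluded; the returned
    tuple is ``(table, excluded_networks)``.  Backbone degree distributions
    are taken over kept nodes only.
    """
    rows = []
    excluded = sorted(n for n, g in graphs.items() if g.n_edges < min_edges)
    for name, g in graphs.items():
        if name in excluded:
            continue
        w_orig = list(g.edges.values())
        d_orig = list(g.degrees().values())
        ks_w, ks_d = {}, {}
        for method in methods:
            key = (name, method)
            if key not in backbones:
                continue
            b = backbones[key]
            if b.n_edges == 0 or b.n_nodes == 0:
                continue
            bw = list(b.edge_weights().values())
            bdeg = [d for _, d in b.to_nx().degree()]
            ks_w[method] = ks_statistic(bw, w_orig)
            ks_d[method] = ks_statistic(bdeg, d_orig)
        if len(ks_w) < 2:
            continue
        rw = rank_methods(ks_w)
        rd = rank_methods(ks_d)
        for method in sorted(ks_w):
            rows.append({"network": name, "method": method,
                         "ks_weight": ks_w[method], "ks_degree": ks_d[method],
                         "rank_weight": rw[method], "rank_degree": rd[method]})
    table = pd.DataFrame(rows, columns=["network", "method", "ks_weight",
                                        "ks_degree", "rank_weight", "rank_degree"])
    return table, excluded


def derive_behavior_matrix(global_table: pd.DataFrame, thresholds: dict | None = None):
    """Qualitative method × property verdicts from the global-property table.

    Verdicts: ``consistent_yes`` / ``network_dependent`` / ``consistent_no``,
    with the numeric thresholds that operationalize them (see
    :data:`DEFAULT_THRESHOLDS`) echoed in the returned frame's ``attrs``.
    Networks where a normalized value is undefined are excluded from that
    property's percentage base.
    """
    if global_table.empty:
        raise ValueError("derive_behavior_matrix requires a nonempty global table")
    th = dict(DEFAULT_THRESHOLDS)
    th.update(thresholds or {})
    rows = []
    for method, sub in global_table.groupby("method"):
        verdicts = {"method": method}
        ef = sub[sub["property"] == "edge_fraction"]["raw"].dropna()
        if len(ef):
            frac_heavy = float((ef <= th["heavy_edge_fraction"]).mean())
            frac_light = float((ef > th["heavy_edge_fraction"]).mean())
            if frac_heavy >= th["consistency"]:
                verdicts["heavy_filtering"] = "consistent_yes"
            elif frac_light >= th["consistency"]:
                verdicts["heavy_filtering"] = "consistent_no"
            else:
                verdicts["heavy_filtering"] = "network_dependent"
        else:
            verdicts["heavy_filtering"] = "undefined"
        for prop, source in _BEHAVIOR_SOURCE.items():
            vals = sub[sub["property"] == source]["normalized"].dropna()
            if not len(vals):
                verdicts[prop] = "undefined"
                continue
            if float((vals >= th["preserved"]).mean()) >= th["consistency"]:
                verdicts[prop] = "consistent_yes"
            elif float((vals <= th["lost"]).mean()) >= th["consistency"]:
                verdicts[prop] = "consistent_no"
            else:
                verdicts[prop] = "network_dependent"
        rows.append(verdicts)
    out = pd.DataFrame(rows, columns=["method", *BEHAVIOR_PROPERTIES]).set_index("method")
    out.attrs["thresholds"] = th
    return out


def _config_hash(config: BenchConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _write_csv(df: pd.DataFrame, path: Path, index=False) -> None:
    df.to_csv(path, index=index, lineterminator="\n", float_format="%.12g")


def run_bench(config: BenchConfig) -> dict:
    """Run all four experiments and write the output tables.

    Writes ``similarity.csv``, ``similarity_mean.csv``/``_std.csv``,
    ``overlap_mean.csv``/``_std.csv``, ``correlation.csv``, ``global.csv``,
    ``distributions.csv``, ``behavior_matrix.csv`` and ``provenance.json``
    under ``config.out_dir``.  Returns the in-memory tables.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()
    graphs = load_networks(config)
    backbones, failures = extract_all(graphs, config)

    sim_long, jm, js, om, os_ = run_similarity(graphs, backbones, config.methods)
    corr = run_edge_correlation(graphs, backbones, config.methods, config.distance_map)
    glob = run_global_properties(graphs, backbones, config.methods, config.entropy_mode)
    dist, excluded = run_distribution_comparison(
        graphs, backbones, config.methods, config.min_edges_for_distribution
    )
    behavior = derive_behavior_matrix(glob, config.thresholds)

    _write_csv(sim_long, out / "similarity.csv")
    _write_csv(jm, out / "similarity_mean.csv", index=True)
    _write_csv(js, out / "similarity_std.csv", index=True)
    _write_csv(om, out / "overlap_mean.csv", index=True)
    _write_csv(os_, out / "overlap_std.csv", index=True)
    _write_csv(corr, out / "correlation.csv")
    _write_csv(glob, out / "global.csv")
    _write_csv(dist, out / "distributions.csv")
    _write_csv(behavior.reset_index(), out / "behavior_matrix.csv")

    provenance = {
        "config": config.to_dict(),
        "config_hash": _config_hash(config),
        "netbackbone_version": __version__,
        "n_networks": len(graphs),
        "networks": sorted(graphs),
        "failures": [list(f) for f in failures],
        "distribution_excluded": excluded,
        "behavior_thresholds": behavior.attrs["thresholds"],
        "runtime_s": round(time.perf_counter() - t0, 3),
    }
    with open(out / "provenance.json", "w", encoding="utf-8") as fh:
        json.dump(provenance, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return {
        "graphs": graphs,
        "backbones": backbones,
        "failures": failures,
        "similarity": sim_long,
        "jaccard_mean": jm,
        "jaccard_std": js,
        "overlap_mean": om,
        "overlap_std": os_,
        "correlation": corr,
        "global": glob,
        "distributions": dist,
        "distribution_excluded": excluded,
        "behavior": behavior,
    }
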