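"""Shared fixtures: deterministic small graphs and one session-wide pair of
full benchmark runs (the pipeline is exercised once and reused by the tests
that inspect its tables and its determinism)."""

from __future__ import annotations

import numpy as np
import pytest

from netbackbone.synthetic import SyntheticSpec, WeightLaw, fixtures as _fixtures


@pytest.fixture(scope="session")
def small_graphs():
    return _fixtures()


@pytest.fixture(scope="session")
def triangle(small_graphs):
    return small_graphs["triangle_321"]


def random_graph(seed: int, n_lo=5, n_hi=30, p_lo=0.15, p_hi=0.9,
                 law=("uniform", (1.0, 10.0))):
    """One seeded Erdős–Rényi weighted graph with all-distinct weights."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(n_lo, n_hi + 1))
    p = float(rng.uniform(p_lo, p_hi))
    spec = SyntheticSpec(
        "random_uniform", n, {"p": p}, WeightLaw(*law),
        distinct_weights=True, seed=int(rng.integers(2**31)),
    )
    from netbackbone.synthetic import generate

    return generate(spec)


@pytest.fixture(scope="session")
def bench_pair(tmp_path_factory):
    """Two identical default-panel benchmark runs (used for the experiment
    tables and the byte-determinism check)."""
    from netbackbone.bench import BenchConfig, run_bench

    root = tmp_path_factory.mktemp("bench")
    out1, out2 = root / "run1", root / "run2"
    res1 = run_bench(BenchConfig(out_dir=str(out1), seed=0))
    res2 = run_bench(BenchConfig(out_dir=str(out2), seed=0))
    return {"dir1": out1, "dir2": out2, "res1": res1, "res2": res2}
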