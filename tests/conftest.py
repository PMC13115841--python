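"""Shared fixtures: planted benchmark, its analysis, and small graphs."""

from itertools import combinations

import numpy as np
import pytest

import socionet as sn
from socionet import pipeline


def enumeration_hypergeom(k: int, K: int, n: int, N: int) -> float:
    """Brute-force upper-tail hypergeometric by enumerating all C(N, n)
    draws of size n from a universe of N with K marked items."""
    universe = range(N)
    marked = set(range(K))
    hits = total = 0
    for draw in combinations(universe, n):
        total += 1
        if len(marked.intersection(draw)) >= k:
            hits += 1
    return hits / total


@pytest.fixture(scope="session")
def default_benchmark():
    """Planted-module benchmark at generator defaults (seed 1)."""
    return sn.generate_benchmark()


@pytest.fixture(scope="session")
def benchmark_interactome(default_benchmark):
    return default_benchmark.build_interactome()


@pytest.fixture(scope="session")
def benchmark_analysis(default_benchmark, benchmark_interactome):
    """Full pipeline run on the default benchmark (200 permutations)."""
    return pipeline.analyze(
        benchmark_interactome,
        default_benchmark.seeds,
        default_benchmark.disease,
        n_perm=200,
        seed=0,
    )


@pytest.fixture()
def two_node_interactome():
    return sn.Interactome(genes=("a", "b"), edges={("a", "b"): 900})


def random_er_interactome(n: int, p: float, seed: int) -> sn.Interactome:
    """Small random graph for numerical property checks."""
    rng = np.random.default_rng(seed)
    genes = tuple(f"g{i:03d}" for i in range(n))
    edges = {}
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                edges[(genes[i], genes[j])] = int(rng.integers(400, 1001))
    return sn.Interactome(genes=genes, edges=edges)
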