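"""Shared fixtures and independent oracles.

The oracles here deliberately avoid the package's own code paths: modularity
optima come from exhaustive enumeration of all set partitions, Barber
modularity from a literal double loop over node pairs, and NMI from
scikit-learn's contingency-based implementation.
"""

from __future__ import annotations

from itertools import product

import numpy as np
import pytest

from bicomm import BipartiteGraph, Partition, WeightedGraph


def iter_set_partitions(n: int):
    """Yield every partition of n items as a canonical label array."""
    labels = np.zeros(n, dtype=np.int64)

    def rec(i: int, k: int):
        if i == n:
            yield labels.copy()
            return
        for c in range(k + 1):
            labels[i] = c
            yield from rec(i + 1, max(k, c + 1))

    yield from rec(1, 1)  # item 0 fixed to community 0


def newman_q(A: np.ndarray, labels: np.ndarray) -> float:
    """Direct evaluation of Newman modularity from the definition."""
    W = A.sum() / 2.0
    if W == 0:
        return 0.0
    q = 0.0
    for c in np.unique(labels):
        mask = labels == c
        q += A[np.ix_(mask, mask)].sum() / (2 * W) - (A[mask].sum() / (2 * W)) ** 2
    return q


def brute_force_modularity_optimum(A: np.ndarray) -> tuple[float, np.ndarray]:
    """Global modularity maximum by enumerating all partitions (n <= ~10)."""
    best_q, best = -np.inf, None
    for labels in iter_set_partitions(A.shape[0]):
        q = newman_q(A, labels)
        if q > best_q:
            best_q, best = q, labels
    return best_q, best


def barber_q_double_loop(graph: BipartiteGraph, g1: np.ndarray, g2: np.ndarray) -> float:
    """Literal O(n1*n2) evaluation of Barber bipartite modularity."""
    B = graph.biadjacency()
    k = B.sum(axis=1)
    d = B.sum(axis=0)
    m = graph.m
    q = 0.0
    for i in range(graph.n1):
        for j in range(graph.n2):
            if g1[i] == g2[j]:
                q += (B[i, j] - k[i] * d[j] / m) / m
    return q


def random_weighted_graph(rng: np.random.Generator, n: int, p: float = 0.5,
                          weighted: bool = False) -> WeightedGraph:
    """Random symmetric graph with at least one edge."""
    while True:
        A = (rng.random((n, n)) < p).astype(float)
        if weighted:
            A *= rng.integers(1, 5, size=(n, n))
        A = np.triu(A, 1)
        A = A + A.T
        if A.sum() > 0:
            return WeightedGraph(A)


def random_bipartite(rng: np.random.Generator, n1: int, n2: int, p: float = 0.4) -> BipartiteGraph:
    while True:
        B = (rng.random((n1, n2)) < p).astype(int)
        if B.sum() > 0:
            return BipartiteGraph.from_biadjacency(B)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20140516)


@pytest.fixture
def two_triangles() -> WeightedGraph:
    """Two disjoint triangles with unit weights."""
    A = np.zeros((6, 6))
    for a, b in [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)]:
        A[a, b] = A[b, a] = 1.0
    return WeightedGraph(A)


@pytest.fixture
def two_cliques_bridge() -> WeightedGraph:
    """Two 4-cliques joined by a single edge."""
    A = np.zeros((8, 8))
    for grp in (range(4), range(4, 8)):
        for a in grp:
            for b in grp:
                if a < b:
                    A[a, b] = A[b, a] = 1.0
    A[3, 4] = A[4, 3] = 1.0
    return WeightedGraph(A)


@pytest.fixture
def two_block_bipartite() -> BipartiteGraph:
    """Block-diagonal bipartite graph: two complete 2x2 blocks."""
    B = np.zeros((4, 4), dtype=int)
    B[:2, :2] = 1
    B[2:, 2:] = 1
    return BipartiteGraph.from_biadjacency(B)
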