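"""One-mode constructions from a bipartite network.

Two ways to hand a bipartite network to a one-mode community detector:

* ``project`` -- the weighted one-mode projection.  For mode 1 this is
  B @ B.T: entry (i, i') counts the mode-2 neighbors shared by mode-1 nodes
  i and i' (how many teams a pair of artists share).  Mode 2 is B.T @ B.
  The diagonal of these products counts each node's own memberships, not
  ties, and is dropped.

* ``meta_matrix`` -- the combined representation: the (n1+n2)-square block
  off-diagonal matrix with B in the upper-right block and B.T in the
  lower-left, so one detector partitions both modes simultaneously.
"""

from __future__ import annotations

import numpy as np

from .graph import BipartiteGraph, WeightedGraph

__all__ = ["project", "meta_matrix"]


def project(graph: BipartiteGraph, mode: int) -> WeightedGraph:
    """Weighted one-mode projection of ``graph`` onto ``mode`` (1 or 2).

    Returns the symmetric integer matrix of shared-neighbor counts with the
    diagonal (own membership counts) zeroed.
    """
    B = graph.biadjacency().astype(np.float64)  # BLAS path; counts stay exact
    if mode == 1:
        W = B @ B.T
        tag = "mode1-projection"
    elif mode == 2:
        W = B.T @ B
        tag = "mode2-projection"
    else:
        raise ValueError(f"mode must be 1 or 2, got {mode!r}")
    W = np.rint(W).astype(np.int64)
    np.fill_diagonal(W, 0)
    return WeightedGraph(W, mode=tag)


def meta_matrix(graph: BipartiteGraph) -> WeightedGraph:
    """Block off-diagonal meta-matrix [[0, B], [B.T, 0]].

    Node order is mode-1 nodes ``0..n1-1`` followed by mode-2 nodes
    ``n1..n1+n2-1``.
    """
    B = graph.biadjacency()
    n1, n2 = graph.n1, graph.n2
    M = np.zeros((n1 + n2, n1 + n2), dtype=np.int64)
    M[:n1, n1:] = B
    M[n1:, :n1] = B.T
    return WeightedGraph(M, mode="meta")
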