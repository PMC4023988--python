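"""Random-walk community detection on weighted one-mode graphs.

The single detection backend used by both bipartite pipelines is walktrap
(Pons & Latapy): nodes are agglomeratively merged by the similarity of their
t-step random-walk distributions, and the dendrogram is cut at the level of
maximum Newman modularity.  Short walks (t = 4 by default) are long enough to
feel community structure but short enough not to mix over the whole graph.

The agglomeration itself is delegated to python-igraph's reference
implementation (weighted, deterministic); the dendrogram bookkeeping, the
per-level modularity curve and the best-cut selection are done here so that
the cut criterion is the exact Newman Q defined in :func:`modularity`,
computed globally (also for disconnected graphs, where igraph merges only
within components and isolated nodes stay singletons).

Any callable ``(WeightedGraph) -> Partition`` can stand in as a detection
backend in the pipeline functions; walktrap is the one that ships.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import igraph as ig
import numpy as np

from .graph import Partition, WeightedGraph

__all__ = ["Dendrogram", "walktrap_dendrogram", "walktrap_communities", "modularity",
           "CommunityDetector"]

#: Interface for pluggable detection backends.
CommunityDetector = Callable[[WeightedGraph], Partition]


def modularity(graph: WeightedGraph, partition: Partition) -> float:
    """Newman modularity Q of a partition of a weighted graph.

    ``Q = sum_c (w_c / W - (s_c / 2W)**2)`` where ``w_c`` is the weight
    inside community c, ``s_c`` the summed weighted degree of c, and ``W``
    the total edge weight.  Q = 0 for the all-in-one partition; a graph with
    no edges scores 0 under every partition.
    """
    if partition.n != graph.n:
        raise ValueError(f"partition covers {partition.n} nodes, graph has {graph.n}")
    A = graph.weights
    W = A.sum() / 2.0
    if W == 0:
        return 0.0
    q = 0.0
    for c in range(partition.k):
        mask = partition.labels == c
        w_c = A[np.ix_(mask, mask)].sum() / 2.0
        s_c = A[mask].sum()
        q += w_c / W - (s_c / (2.0 * W)) ** 2
    return float(q)


@dataclass(frozen=True)
class Dendrogram:
    """Agglomerative merge history with its global-modularity curve.

    ``merges[i] = (a, b, new_id)`` merges communities a and b into community
    ``n + i`` (initial communities are the nodes ``0..n-1``).  ``q_levels[L]``
    is the Newman modularity after the first L merges; ``best_level``
    maximizes it (first maximum on ties, favoring more communities).
    """

    n: int
    merges: tuple[tuple[int, int, int], ...]
    q_levels: tuple[float, ...]
    best_level: int

    def membership(self, level: int | None = None) -> Partition:
        """Partition after the first ``level`` merges (default: best cut)."""
        if level is None:
            level = self.best_level
        if not 0 <= level <= len(self.merges):
            raise ValueError(f"level must be in [0, {len(self.merges)}]")
        owner = np.arange(self.n + level, dtype=np.int64)

        def find(x: int) -> int:
            while owner[x] != x:
                owner[x] = owner[owner[x]]
                x = owner[x]
            return x

        for a, b, new in self.merges[:level]:
            owner[find(a)] = new
            owner[find(b)] = new
        return Partition(np.array([find(i) for i in range(self.n)]))


def walktrap_dendrogram(graph: WeightedGraph, t: int = 4) -> Dendrogram:
    """Full walktrap dendrogram of a weighted graph, with walk length ``t``."""
    if graph.n < 1:
        raise ValueError("graph must have at least one node")
    if t < 1:
        raise ValueError("walk length must be >= 1")
    A = graph.weights
    iu, ju = np.nonzero(np.triu(A, k=1))
    if iu.size == 0:  # edgeless: every node is its own community
        return Dendrogram(graph.n, (), (0.0,), 0)
    g = ig.Graph(n=graph.n, edges=list(zip(iu.tolist(), ju.tolist())))
    weights = A[iu, ju].tolist()
    vd = g.community_walktrap(weights=weights, steps=t)
    merges = tuple((a, b, graph.n + idx) for idx, (a, b) in enumerate(vd.merges))

    # incremental global-modularity curve over dendrogram levels
    W = A.sum() / 2.0
    strength = np.zeros(graph.n + len(merges))
    within = np.zeros(graph.n + len(merges))
    strength[: graph.n] = A.sum(axis=1)
    neigh: list[dict[int, float]] = [
        {int(j): float(A[i, j]) for j in np.nonzero(A[i])[0]} for i in range(graph.n)
    ]
    neigh += [{} for _ in merges]
    q = float(-np.sum((strength[: graph.n] / (2 * W)) ** 2))
    q_levels = [q]
    for a, b, new in merges:
        cross = neigh[a].get(b, 0.0)
        within[new] = within[a] + within[b] + cross
        strength[new] = strength[a] + strength[b]
        q += within[new] / W - (strength[new] / (2 * W)) ** 2
        q -= within[a] / W - (strength[a] / (2 * W)) ** 2
        q -= within[b] / W - (strength[b] / (2 * W)) ** 2
        merged = neigh[a]
        for key, val in neigh[b].items():
            merged[key] = merged.get(key, 0.0) + val
        merged.pop(a, None)
        merged.pop(b, None)
        neigh[new] = merged
        neigh[a] = neigh[b] = {}
        for key in merged:  # re-point other communities' references at `new`
            d = neigh[key]
            d[new] = d.pop(a, 0.0) + d.pop(b, 0.0)
        q_levels.append(q)
    best = int(np.argmax(q_levels))
    return Dendrogram(graph.n, merges, tuple(q_levels), best)


def walktrap_communities(graph: WeightedGraph, t: int = 4) -> Partition:
    """Modularity-maximizing walktrap partition of a weighted graph.

    Isolated nodes become singleton communities; on disconnected graphs
    agglomeration runs per component and the cut maximizes global modularity.
    """
    return walktrap_dendrogram(graph, t=t).membership()
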