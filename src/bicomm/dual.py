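"""End-to-end bipartite community detection pipelines.

Two strategies for recovering the community structure of both modes of a
bipartite network:

* **dual-projection** (:func:`detect_dual`): detect communities in each
  mode's weighted projection separately, then match the two per-mode
  solutions across modes so as to maximize Barber's bipartite modularity
  Q_B -- i.e. combine them "in a fashion that maximizes within-community
  ties".

* **combined** (:func:`detect_combined`): detect communities once on the
  block off-diagonal meta-matrix, so both modes are partitioned
  simultaneously and the cross-mode matching is induced rather than
  searched.

Barber's Q_B is the bipartite analogue of Newman's Q: for biadjacency B with
mode-1 degrees k_i, mode-2 degrees d_j and m edges,

    Q_B = (1/m) * sum_{i,j} (B_ij - k_i d_j / m) * delta(g_i, g_j)

where delta fires when mode-1 node i and mode-2 node j carry the same joint
community label.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .graph import BipartiteGraph, Partition
from .projections import meta_matrix, project
from .walktrap import walktrap_communities

__all__ = ["JointPartition", "barber_modularity", "combine_partitions",
           "detect_dual", "detect_combined"]

# beyond this many enumerated cross-mode assignments, fall back to greedy
_EXHAUSTIVE_CAP = 300_000


@dataclass(frozen=True)
class JointPartition:
    """Per-mode partitions plus a cross-mode community matching.

    ``joint1[c]`` / ``joint2[c]`` give the shared joint label of mode-1 /
    mode-2 community ``c``; communities of different modes mapped to the same
    joint label form one bipartite community.  Unmatched communities keep a
    joint label of their own.
    """

    partition1: Partition
    partition2: Partition
    joint1: np.ndarray
    joint2: np.ndarray
    barber_q: float = float("nan")

    def __post_init__(self) -> None:
        j1 = np.asarray(self.joint1, dtype=np.int64)
        j2 = np.asarray(self.joint2, dtype=np.int64)
        if j1.size != self.partition1.k or j2.size != self.partition2.k:
            raise ValueError("matching must map every community of each mode")
        object.__setattr__(self, "joint1", j1)
        object.__setattr__(self, "joint2", j2)

    def joint_labels(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-node joint labels for mode 1 and mode 2."""
        return self.joint1[self.partition1.labels], self.joint2[self.partition2.labels]

    @property
    def n_joint(self) -> int:
        """Number of distinct joint communities."""
        return np.union1d(self.joint1, self.joint2).size


def barber_modularity(graph: BipartiteGraph, joint: JointPartition) -> float:
    """Barber bipartite modularity Q_B of a matched joint partition."""
    m = graph.m
    if m == 0:
        raise ValueError("Barber modularity is undefined for an edgeless graph")
    if joint.partition1.n != graph.n1 or joint.partition2.n != graph.n2:
        raise ValueError("joint partition must cover all nodes of both modes")
    B = graph.biadjacency()
    k, d = graph.degrees()
    g1, g2 = joint.joint_labels()
    q = 0.0
    for g in np.intersect1d(g1, g2):
        mask1 = g1 == g
        mask2 = g2 == g
        within = B[np.ix_(mask1, mask2)].sum()
        q += (within - k[mask1].sum() * d[mask2].sum() / m) / m
    return float(q)


def _crosstab_gain(graph: BipartiteGraph, p1: Partition, p2: Partition) -> np.ndarray:
    """Q_B gain matrix: G[c1, c2] is the Q_B contribution of co-labeling
    mode-1 community c1 with mode-2 community c2."""
    B = graph.biadjacency()
    k, d = graph.degrees()
    m = graph.m
    ind1 = np.eye(p1.k, dtype=np.int64)[p1.labels]  # n1 x k1 one-hot
    ind2 = np.eye(p2.k, dtype=np.int64)[p2.labels]
    E = ind1.T @ B @ ind2  # edges between community pairs
    K = ind1.T @ k
    D = ind2.T @ d
    return (E - np.outer(K, D) / m) / m


def _assemble(p1: Partition, p2: Partition,
              groups: list[tuple[set[int], set[int]]],
              barber_q: float) -> JointPartition:
    joint1 = np.full(p1.k, -1, dtype=np.int64)
    joint2 = np.full(p2.k, -1, dtype=np.int64)
    order = sorted(groups, key=lambda g: (min(g[0]) if g[0] else p1.k + min(g[1]),
                                          min(g[1]) if g[1] else -1))
    for label, (s1, s2) in enumerate(order):
        for c in s1:
            joint1[c] = label
        for c in s2:
            joint2[c] = label
    return JointPartition(p1, p2, joint1, joint2, barber_q)


def combine_partitions(graph: BipartiteGraph, p1: Partition, p2: Partition) -> JointPartition:
    """Match per-mode community solutions to maximize Barber modularity Q_B.

    The search maps each community of the mode with fewer communities to
    either one community of the other mode (many-to-one allowed) or to an
    unmatched joint label of its own.  Small problems are solved by
    exhaustive enumeration; larger ones by attaching each community to its
    largest-gain cross-mode partner, which is exact here because the Q_B
    objective separates over the smaller mode's labels.  Unmatched
    communities are legal; the result never scores below the all-unmatched
    baseline Q_B = 0.
    """
    if graph.m == 0:
        raise ValueError("cannot combine partitions of an edgeless graph")
    if p1.n != graph.n1 or p2.n != graph.n2:
        raise ValueError("partitions must cover their modes")
    G = _crosstab_gain(graph, p1, p2)
    k1, k2 = p1.k, p2.k
    small_is_1 = k1 <= k2
    k_small, k_big = (k1, k2) if small_is_1 else (k2, k1)
    Gs = G if small_is_1 else G.T  # k_small x k_big

    if k1 * k2 <= 64 and (k_big + 1) ** k_small <= _EXHAUSTIVE_CAP:
        padded = np.hstack([Gs, np.zeros((k_small, 1))])  # column k_big = unmatched
        # product order puts real matches before the unmatched option, so on
        # exact ties a matched assignment wins (single joint community when
        # k1 = k2 = 1); the all-unmatched baseline q = 0 is always enumerated
        best_q, best_assign = -np.inf, None
        for assign in itertools.product(range(k_big + 1), repeat=k_small):
            q = sum(padded[s, t] for s, t in enumerate(assign))
            if q > best_q + 1e-15:
                best_q, best_assign = q, assign
        groups: list[tuple[set[int], set[int]]] = [(set(), {t}) if small_is_1 else ({t}, set())
                                                   for t in range(k_big)]
        for s, t in enumerate(best_assign):
            if t == k_big:  # unmatched: own joint label
                groups.append(({s}, set()) if small_is_1 else (set(), {s}))
            else:
                (groups[t][0] if small_is_1 else groups[t][1]).add(s)
        return _assemble(p1, p2, groups, float(best_q))

    # greedy path: within this search space Q_B is separable per smaller-mode
    # label, so attaching each label to its largest-gain partner (or leaving
    # it unmatched when every gain is negative) is already the exact optimum
    groups = [(set(), {t}) if small_is_1 else ({t}, set()) for t in range(k_big)]
    q_total = 0.0
    for s in range(k_small):
        t = int(np.argmax(Gs[s]))  # smallest index wins ties
        if Gs[s, t] >= 0.0:
            (groups[t][0] if small_is_1 else groups[t][1]).add(s)
            q_total += Gs[s, t]
        else:
            groups.append(({s}, set()) if small_is_1 else (set(), {s}))
    return _assemble(p1, p2, groups, float(q_total))


def detect_dual(graph: BipartiteGraph, t: int = 4, detector=None) -> JointPartition:
    """Dual-projection pipeline: walktrap on each weighted projection, then
    Q_B-maximizing cross-mode matching."""
    if graph.m == 0:
        raise ValueError("graph must have at least one edge")
    detect = detector or (lambda wg: walktrap_communities(wg, t=t))
    p1 = detect(project(graph, 1))
    p2 = detect(project(graph, 2))
    return combine_partitions(graph, p1, p2)


def detect_combined(graph: BipartiteGraph, t: int = 4, detector=None) -> JointPartition:
    """Combined pipeline: walktrap once on the meta-matrix; the partition is
    split at n1 into per-mode partitions and communities spanning both modes
    keep a shared joint label (the matching is induced, not searched)."""
    if graph.m == 0:
        raise ValueError("graph must have at least one edge")
    detect = detector or (lambda wg: walktrap_communities(wg, t=t))
    meta = detect(meta_matrix(graph))
    lab1 = meta.labels[: graph.n1]
    lab2 = meta.labels[graph.n1:]
    p1, p2 = Partition(lab1), Partition(lab2)
    joint1 = np.array([lab1[p1.labels == c][0] for c in range(p1.k)], dtype=np.int64)
    joint2 = np.array([lab2[p2.labels == c][0] for c in range(p2.k)], dtype=np.int64)
    jp = JointPartition(p1, p2, joint1, joint2)
    return JointPartition(p1, p2, joint1, joint2, barber_modularity(graph, jp))
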