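"""Bipartite and one-mode graph containers with TSV / Matrix Market I/O.

A bipartite (two-mode) network links two disjoint node sets -- e.g. genes to
samples, people to committees, artists to teams -- with edges only between the
sets.  Internally everything is 0-based and binary: the network is fully
described by its n1 x n2 biadjacency matrix B with B[i, j] = 1 iff mode-1
node i is tied to mode-2 node j.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import scipy.io
import scipy.sparse

logger = logging.getLogger(__name__)

__all__ = [
    "BipartiteGraph",
    "WeightedGraph",
    "Partition",
    "read_bipartite_edgelist",
    "write_bipartite_edgelist",
    "read_biadjacency",
    "write_biadjacency",
    "write_partition",
    "read_partition",
]


@dataclass(frozen=True)
class BipartiteGraph:
    """A binary bipartite network.

    Parameters
    ----------
    n1, n2
        Number of mode-1 and mode-2 nodes.
    edges
        Set of ``(i, j)`` pairs, ``0 <= i < n1``, ``0 <= j < n2``.
    labels1, labels2
        Optional original node identifiers per mode (index -> label).
    """

    n1: int
    n2: int
    edges: frozenset[tuple[int, int]]
    labels1: tuple[str, ...] | None = None
    labels2: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.n1 < 1 or self.n2 < 1:
            raise ValueError("both modes need at least one node")
        object.__setattr__(self, "edges", frozenset(self.edges))
        for i, j in self.edges:
            if not (0 <= i < self.n1 and 0 <= j < self.n2):
                raise ValueError(f"edge ({i}, {j}) out of range for {self.n1}x{self.n2}")
        if self.labels1 is not None and len(self.labels1) != self.n1:
            raise ValueError("labels1 length must equal n1")
        if self.labels2 is not None and len(self.labels2) != self.n2:
            raise ValueError("labels2 length must equal n2")

    @property
    def m(self) -> int:
        """Edge count."""
        return len(self.edges)

    @property
    def density(self) -> float:
        """|edges| / (n1 * n2)."""
        return self.m / (self.n1 * self.n2)

    def biadjacency(self) -> np.ndarray:
        """Dense n1 x n2 binary biadjacency matrix B."""
        B = np.zeros((self.n1, self.n2), dtype=np.int64)
        if self.edges:
            idx = np.asarray(sorted(self.edges))
            B[idx[:, 0], idx[:, 1]] = 1
        return B

    def degrees(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-node degree vectors ``(k, d)`` for mode 1 and mode 2."""
        B = self.biadjacency()
        return B.sum(axis=1), B.sum(axis=0)

    @classmethod
    def from_biadjacency(cls, B: np.ndarray | scipy.sparse.spmatrix,
                         labels1: Sequence[str] | None = None,
                         labels2: Sequence[str] | None = None) -> "BipartiteGraph":
        B = np.asarray(scipy.sparse.csr_matrix(B).todense()) if scipy.sparse.issparse(B) else np.asarray(B)
        if B.ndim != 2:
            raise ValueError("biadjacency matrix must be 2-dimensional")
        if not np.isin(B, (0, 1)).all():
            raise ValueError("biadjacency matrix must be binary")
        ii, jj = np.nonzero(B)
        return cls(B.shape[0], B.shape[1],
                   frozenset(zip(ii.tolist(), jj.tolist())),
                   tuple(labels1) if labels1 is not None else None,
                   tuple(labels2) if labels2 is not None else None)


@dataclass(frozen=True)
class WeightedGraph:
    """A square symmetric non-negative weighted graph with zero diagonal.

    Holds one-mode projections (shared-neighbor counts) and the block
    off-diagonal meta-matrix of a bipartite network.  The diagonal is zero by
    construction: self-ties carry no community information.
    """

    weights: np.ndarray
    mode: str | None = None  # "mode1-projection" | "mode2-projection" | "meta"

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weights must be a square matrix")
        if not np.array_equal(w, w.T):
            raise ValueError("weights must be symmetric")
        if np.any(np.diag(w) != 0):
            raise ValueError("diagonal must be zero")
        if np.any(w < 0):
            raise ValueError("weights must be non-negative")
        object.__setattr__(self, "weights", w)

    @property
    def n(self) -> int:
        return self.weights.shape[0]

    @property
    def total_weight(self) -> float:
        """Sum of edge weights (each undirected edge counted once)."""
        return float(self.weights.sum()) / 2.0


@dataclass(frozen=True)
class Partition:
    """Assignment of every node of one node set to exactly one community.

    Labels are canonicalized to ``0..k-1`` in order of first appearance, so
    two partitions are equal iff they induce the same grouping.
    """

    labels: np.ndarray
    k: int = field(init=False)

    def __post_init__(self) -> None:
        raw = np.asarray(self.labels)
        if raw.ndim != 1 or raw.size == 0:
            raise ValueError("labels must be a non-empty 1-d sequence")
        _, canon = np.unique(raw, return_inverse=True)
        # np.unique sorts; remap to first-appearance order
        order = {}
        out = np.empty(raw.size, dtype=np.int64)
        for pos, lab in enumerate(canon.tolist()):
            if lab not in order:
                order[lab] = len(order)
            out[pos] = order[lab]
        object.__setattr__(self, "labels", out)
        object.__setattr__(self, "k", len(order))

    @property
    def n(self) -> int:
        return self.labels.size

    def __eq__(self, other: object) -> bool:
        return isinstance(other, Partition) and np.array_equal(self.labels, other.labels)

    def __hash__(self) -> int:
        return hash(self.labels.tobytes())

    def sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.k)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _parse_rows(lines: Iterable[str]) -> list[tuple[str, str]]:
    rows: list[tuple[str, str]] = []
    for lineno, line in enumerate(lines, start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        parts = stripped.split("\t")
        if len(parts) == 1:  # tolerate whitespace-delimited files
            parts = stripped.split()
        if len(parts) < 2:
            raise ValueError(f"line {lineno}: expected at least 2 columns, got {len(parts)!r}")
        rows.append((parts[0], parts[1]))
    return rows


def read_bipartite_edgelist(path: str | Path) -> BipartiteGraph:
    """Read a two-column TSV edge list (mode-1 id, mode-2 id).

    Node ids may be arbitrary strings; they are mapped to 0-based indices in
    stable sorted order.  Duplicate rows are collapsed with a warning.
    ``#``-prefixed lines are treated as comments/headers.
    """
    text = Path(path).read_text()
    rows = _parse_rows(text.splitlines())
    if not rows:
        raise ValueError(f"{path}: no edges found")
    if len(rows) != len(set(rows)):
        logger.warning("%s: %d duplicate edge rows collapsed", path, len(rows) - len(set(rows)))
    ids1 = sorted({r[0] for r in rows})
    ids2 = sorted({r[1] for r in rows})
    idx1 = {v: i for i, v in enumerate(ids1)}
    idx2 = {v: i for i, v in enumerate(ids2)}
    edges = frozenset((idx1[a], idx2[b]) for a, b in rows)
    return BipartiteGraph(len(ids1), len(ids2), edges, tuple(ids1), tuple(ids2))


def write_bipartite_edgelist(graph: BipartiteGraph, path: str | Path) -> None:
    """Write the edge list as TSV, using stored node labels when present."""
    lab1 = graph.labels1 or tuple(str(i) for i in range(graph.n1))
    lab2 = graph.labels2 or tuple(str(j) for j in range(graph.n2))
    with open(path, "w") as fh:
        fh.write("#source\ttarget\n")
        for i, j in sorted(graph.edges):
            fh.write(f"{lab1[i]}\t{lab2[j]}\n")


def read_biadjacency(path: str | Path) -> BipartiteGraph:
    """Read a biadjacency matrix from Matrix Market (.mtx) or dense CSV."""
    path = Path(path)
    if path.suffix == ".mtx":
        B = scipy.io.mmread(str(path))
    else:
        B = np.loadtxt(path, delimiter=",", ndmin=2)
    return BipartiteGraph.from_biadjacency(B)


def write_biadjacency(graph: BipartiteGraph, path: str | Path) -> None:
    """Write the biadjacency matrix as Matrix Market (.mtx) or dense CSV."""
    path = Path(path)
    B = graph.biadjacency()
    if path.suffix == ".mtx":
        scipy.io.mmwrite(str(path), scipy.sparse.coo_matrix(B))
    else:
        np.savetxt(path, B, fmt="%d", delimiter=",")


def write_partition(partition1: Partition, partition2: Partition,
                    path: str | Path,
                    labels1: Sequence[str] | None = None,
                    labels2: Sequence[str] | None = None) -> None:
    """Write per-mode community assignments as TSV (node_id, mode, community).

    Rows are ordered mode 1 before mode 2, node index ascending.
    """
    if partition1.n == 0 or partition2.n == 0:
        raise ValueError("partitions must cover both modes")
    lab1 = labels1 or tuple(str(i) for i in range(partition1.n))
    lab2 = labels2 or tuple(str(j) for j in range(partition2.n))
    if len(lab1) != partition1.n or len(lab2) != partition2.n:
        raise ValueError("label count must match partition size")
    with open(path, "w") as fh:
        fh.write("#node_id\tmode\tcommunity\n")
        for i in range(partition1.n):
            fh.write(f"{lab1[i]}\t1\t{partition1.labels[i]}\n")
        for j in range(partition2.n):
            fh.write(f"{lab2[j]}\t2\t{partition2.labels[j]}\n")


def read_partition(path: str | Path) -> tuple[Partition, Partition]:
    """Read back a partition TSV written by :func:`write_partition`."""
    rows = []
    for line in Path(path).read_text().splitlines():
        s = line.strip()
        if not s or s.startswith("#"):
            continue
        node, mode, comm = s.split("\t")
        rows.append((int(mode), node, int(comm)))
    lab1 = [c for mode, _, c in rows if mode == 1]
    lab2 = [c for mode, _, c in rows if mode == 2]
    if not lab1 or not lab2:
        raise ValueError(f"{path}: missing one of the modes")
    return Partition(np.array(lab1)), Partition(np.array(lab2))
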