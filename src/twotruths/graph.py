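"""Graph data model, file I/O and structural utilities.

Graphs here are simple: undirected, unweighted, loopless.  The adjacency
matrix is therefore binary, symmetric (``A = A.T``) and hollow
(``diag(A) = 0``).  Vertices may carry two categorical label tracks,
hemisphere ({Left, Right}) and tissue ({Gray, White}), whose pairing gives
the combined four-level track {LG, LW, RG, RW}.

Vertex ids are 0-based, both in memory and in every file format.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components

logger = logging.getLogger(__name__)

__all__ = [
    "Graph",
    "VertexLabels",
    "WeightedGraph",
    "GraphFormatError",
    "read_graph",
    "write_graph",
    "read_labels",
    "write_labels",
    "largest_connected_component",
    "average_graphs",
    "binarize",
]

HEMISPHERES = ("Left", "Right")
TISSUES = ("Gray", "White")


class GraphFormatError(ValueError):
    """Raised when a graph file cannot be parsed or validated."""


@dataclass(frozen=True)
class VertexLabels:
    """Per-vertex categorical label tracks.

    Parameters
    ----------
    hemisphere : array of str
        One of ``{"Left", "Right"}`` per vertex.
    tissue : array of str
        One of ``{"Gray", "White"}`` per vertex.
    """

    hemisphere: np.ndarray
    tissue: np.ndarray

    def __post_init__(self):
        h = np.asarray(self.hemisphere, dtype=object)
        t = np.asarray(self.tissue, dtype=object)
        object.__setattr__(self, "hemisphere", h)
        object.__setattr__(self, "tissue", t)
        if h.shape != t.shape or h.ndim != 1:
            raise ValueError("hemisphere and tissue must be 1-D of equal length")
        if not set(h).issubset(HEMISPHERES):
            raise ValueError(f"hemisphere values must be in {HEMISPHERES}")
        if not set(t).issubset(TISSUES):
            raise ValueError(f"tissue values must be in {TISSUES}")

    def __len__(self) -> int:
        return len(self.hemisphere)

    @property
    def combined(self) -> np.ndarray:
        """Deterministic pairing of the two tracks: 'LG', 'LW', 'RG', 'RW'."""
        return np.array(
            [h[0] + t[0] for h, t in zip(self.hemisphere, self.tissue)],
            dtype=object,
        )

    def subset(self, idx: np.ndarray) -> "VertexLabels":
        return VertexLabels(self.hemisphere[idx], self.tissue[idx])


def _check_structural(A: sp.spmatrix, binary: bool = True) -> None:
    if A.shape[0] != A.shape[1]:
        raise ValueError("adjacency must be square")
    if (A != A.T).nnz != 0:
        raise ValueError("adjacency must be symmetric")
    if A.diagonal().any():
        raise ValueError("adjacency must be hollow (zero diagonal)")
    if binary:
        if A.nnz and not np.isin(A.data, (0, 1)).all():
            raise ValueError("adjacency entries must be in {0, 1}")
    else:
        if A.nnz and (A.data < 0).any():
            raise ValueError("weights must be nonnegative")


@dataclass
class Graph:
    """Simple undirected unweighted graph with optional vertex labels."""

    n: int
    adjacency: sp.csr_matrix
    labels: Optional[VertexLabels] = None

    def __post_init__(self):
        A = sp.csr_matrix(self.adjacency, dtype=np.int8)
        A.eliminate_zeros()
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if A.shape != (self.n, self.n):
            raise ValueError("adjacency shape does not match n")
        _check_structural(A, binary=True)
        if self.labels is not None and len(self.labels) != self.n:
            raise ValueError("labels length does not match n")
        self.adjacency = A

    @classmethod
    def from_edges(
        cls,
        n: int,
        edges: Sequence[tuple[int, int]],
        labels: Optional[VertexLabels] = None,
    ) -> "Graph":
        """Build a graph from an iterable of (i, j) pairs.

        Duplicate edges are collapsed, self-loops dropped, and the
        adjacency symmetrized.
        """
        edges = np.asarray(list(edges), dtype=np.int64).reshape(-1, 2)
        n_loops = 0
        if len(edges):
            if edges.min() < 0:
                raise GraphFormatError("negative vertex id in edge list")
            if edges.max() >= n:
                raise GraphFormatError("vertex id exceeds n")
            loops = edges[:, 0] == edges[:, 1]
            n_loops = int(loops.sum())
            edges = edges[~loops]
        if n_loops:
            logger.info("dropped %d self-loop(s)", n_loops)
        i = np.concatenate([edges[:, 0], edges[:, 1]])
        j = np.concatenate([edges[:, 1], edges[:, 0]])
        A = sp.coo_matrix((np.ones(len(i), dtype=np.int8), (i, j)), shape=(n, n))
        A = A.tocsr()
        A.data[:] = 1  # collapse duplicates
        return cls(n=n, adjacency=A, labels=labels)

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.nnz // 2)

    def edge_array(self) -> np.ndarray:
        """Canonical edge list: each edge once, smaller id first, row-sorted."""
        coo = sp.triu(self.adjacency, k=1).tocoo()
        e = np.column_stack([coo.row, coo.col])
        order = np.lexsort((e[:, 1], e[:, 0]))
        return e[order]

    def degrees(self) -> np.ndarray:
        return np.asarray(self.adjacency.sum(axis=1)).ravel().astype(np.int64)


@dataclass
class WeightedGraph:
    """Symmetric hollow nonnegative-weight graph (e.g. a composite average)."""

    n: int
    weights: sp.csr_matrix

    def __post_init__(self):
        W = sp.csr_matrix(self.weights, dtype=np.float64)
        W.eliminate_zeros()
        if W.shape != (self.n, self.n):
            raise ValueError("weights shape does not match n")
        _check_structural(W, binary=False)
        self.weights = W


# ---------------------------------------------------------------------------
# I/O


def _parse_edge_list(path: str) -> tuple[np.ndarray, int]:
    """Return (edges, max_id+1). Lines: "i<TAB>j[<TAB>w]", '#' comments."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise GraphFormatError(
                    f"{path}:{lineno}: expected at least two columns, got {line!r}"
                )
            try:
                i, j = int(parts[0]), int(parts[1])
            except ValueError as exc:
                raise GraphFormatError(
                    f"{path}:{lineno}: non-integer vertex id in {line!r}"
                ) from exc
            if i < 0 or j < 0:
                raise GraphFormatError(f"{path}:{lineno}: negative vertex id")
            rows.append((i, j))
    edges = np.asarray(rows, dtype=np.int64).reshape(-1, 2)
    n_min = int(edges.max()) + 1 if len(edges) else 1
    return edges, n_min


def read_graph(
    path: str, format: str = "edge-list", n_hint: Optional[int] = None
) -> Graph:
    """Read a simple graph from an edge-list TSV or Matrix Market file.

    Self-loops are dropped (with a logged count), duplicate edges collapsed
    and the adjacency symmetrized.  ``n_hint`` extends the vertex set beyond
    the largest id seen in the file (isolated trailing vertices).
    """
    if format == "edge-list":
        edges, n_min = _parse_edge_list(path)
        n = max(n_min, n_hint or 0)
        return Graph.from_edges(n, edges)
    if format == "matrix-market":
        M = scipy.io.mmread(path)
        if M.shape[0] != M.shape[1]:
            raise GraphFormatError("matrix-market adjacency must be square")
        M = sp.csr_matrix(M)
        M.setdiag(0)
        M = ((M + M.T) != 0).astype(np.int8)
        n = M.shape[0]
        if n_hint and n_hint > n:
            M = sp.csr_matrix(
                sp.block_diag([M, sp.csr_matrix((n_hint - n, n_hint - n))])
            )
            n = n_hint
        return Graph(n=n, adjacency=M)
    raise ValueError(f"unknown format {format!r}")


def write_graph(g: Graph, path: str, format: str = "edge-list") -> None:
    """Write a graph canonically (each edge once, smaller id first, sorted)."""
    if format == "edge-list":
        edges = g.edge_array()
        with open(path, "w") as fh:
            fh.write(f"# n={g.n} edges={len(edges)}\n")
            for i, j in edges:
                fh.write(f"{i}\t{j}\n")
    elif format == "matrix-market":
        # pass a handle so scipy honors the exact path (no .mtx appended)
        with open(path, "wb") as fh:
            scipy.io.mmwrite(fh, g.adjacency.tocoo(), symmetry="symmetric")
    else:
        raise ValueError(f"unknown format {format!r}")


def read_labels(path: str) -> VertexLabels:
    """Read a vertex label TSV with columns vertex_id, hemisphere, tissue."""
    df = pd.read_csv(path, sep="\t", comment="#")
    df = df.sort_values("vertex_id")
    if not np.array_equal(df["vertex_id"].to_numpy(), np.arange(len(df))):
        raise GraphFormatError("vertex_id column must be 0..n-1 exactly once each")
    return VertexLabels(df["hemisphere"].to_numpy(), df["tissue"].to_numpy())


def write_labels(labels: VertexLabels, path: str) -> None:
    pd.DataFrame(
        {
            "vertex_id": np.arange(len(labels)),
            "hemisphere": labels.hemisphere,
            "tissue": labels.tissue,
        }
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Structural utilities


def largest_connected_component(g: Graph) -> tuple[Graph, np.ndarray]:
    """Extract the largest connected component.

    Returns the induced subgraph (labels subset accordingly) and the index
    map old->new with -1 for vertices outside the component.  Ties between
    equally large components go to the one containing the smallest vertex id.
    """
    n_comp, member = connected_components(g.adjacency, directed=False)
    sizes = np.bincount(member, minlength=n_comp)
    keep = int(np.argmax(sizes))  # argmax takes the first (smallest-id) max
    mask = member == keep
    idx = np.flatnonzero(mask)
    index_map = np.full(g.n, -1, dtype=np.int64)
    index_map[idx] = np.arange(len(idx))
    sub = g.adjacency[np.ix_(idx, idx)]
    labels = g.labels.subset(idx) if g.labels is not None else None
    return Graph(n=len(idx), adjacency=sub, labels=labels), index_map


def average_graphs(gs: Sequence[Graph]) -> WeightedGraph:
    """Entrywise mean adjacency of graphs sharing a vertex set."""
    if not gs:
        raise ValueError("need at least one graph to average")
    n = gs[0].n
    if any(g.n != n for g in gs):
        raise ValueError("all graphs must share the same vertex count")
    W = sum(g.adjacency.astype(np.float64) for g in gs) / len(gs)
    return WeightedGraph(n=n, weights=sp.csr_matrix(W))


def binarize(w: WeightedGraph, tau: float = 0.0) -> Graph:
    """Threshold a weighted graph: keep edge (i,j) iff weight > tau."""
    if not (0.0 <= tau < 1.0):
        raise ValueError("tau must be in [0, 1)")
    A = (w.weights > tau).astype(np.int8)
    return Graph(n=w.n, adjacency=sp.csr_matrix(A))
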