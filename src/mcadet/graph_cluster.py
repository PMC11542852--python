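"""Jaccard-reweighted kNN graph on cell coordinates and Leiden partitions.

Cells are embedded in the K-dimensional standard-coordinate space from the
MCA stage.  A directed k-nearest-neighbour graph (Euclidean distance) is
symmetrized and each edge is reweighted by the Jaccard similarity of the two
endpoints' neighbourhoods (shared-nearest-neighbour weighting), after which
Leiden community detection is run once per resolution value on a ladder
(default 0.5, 0.6, ..., 1.4).  The multiple partitions feed the multi-run
rank statistic downstream; no attempt is made to pick a "best" resolution.
"""

from __future__ import annotations

from dataclasses import dataclass

import igraph as ig
import leidenalg
import numpy as np
import scipy.sparse as sp
from sklearn.metrics import pairwise_distances

__all__ = [
    "CellGraph",
    "ClusteringRun",
    "default_resolutions",
    "neighbor_count",
    "build_snn_graph",
    "leiden_partitions",
]


@dataclass
class CellGraph:
    """Weighted undirected SNN graph over cells."""

    n: int
    edges: np.ndarray    # (m, 2) int array of node pairs, u < v
    weights: np.ndarray  # (m,) Jaccard weights in (0, 1]
    k: int               # neighbour count used to build the graph


@dataclass
class ClusteringRun:
    """One Leiden partition at a single resolution."""

    resolution: float
    labels: np.ndarray  # (n,) integers in 1..n_clusters
    n_clusters: int


def default_resolutions() -> list[float]:
    """The default resolution ladder: 0.5 to 1.4 in steps of 0.1 (10 runs)."""
    return [round(0.5 + 0.1 * i, 1) for i in range(10)]


def neighbor_count(n_cells: int, fraction: float = 0.01, floor: int = 10) -> int:
    """k for the kNN graph: a fraction of the cell count with a small floor.

    The fraction is 1% of cells by default; the floor keeps neighbourhoods
    meaningful on small inputs.  Always clamped below ``n_cells``.
    """
    k = max(int(round(fraction * n_cells)), floor)
    return min(k, n_cells - 1)


def _knn_indices(coords: np.ndarray, k: int) -> np.ndarray:
    """Indices of the k nearest neighbours of every point (self excluded).

    Ties in distance are broken by point index so the graph is fully
    deterministic.  Works blockwise to bound memory.
    """
    n = coords.shape[0]
    out = np.empty((n, k), dtype=np.int64)
    block = max(1, int(2e7) // max(n, 1))
    idx = np.arange(n)
    for start in range(0, n, block):
        stop = min(start + block, n)
        d = pairwise_distances(coords[start:stop], coords)
        for i in range(start, stop):
            row = d[i - start]
            order = np.lexsort((idx, row))
            order = order[order != i]
            out[i] = order[:k]
    return out


def build_snn_graph(Phi: np.ndarray, k: int) -> CellGraph:
    """Build the shared-nearest-neighbour graph in the embedding space.

    Each directed kNN edge is kept (symmetrized) and weighted by the Jaccard
    similarity of the endpoints' neighbourhoods.  A point's neighbourhood is
    its k nearest neighbours plus the point itself (size ``k + 1``).
    """
    Phi = np.asarray(Phi, dtype=float)
    n = Phi.shape[0]
    if k <= 0 or k >= n:
        raise ValueError(f"k must satisfy 0 < k < n={n}, got {k}")
    nbrs = _knn_indices(Phi, k)

    # neighbourhood incidence matrix, self included
    rows = np.repeat(np.arange(n), k + 1)
    cols = np.concatenate([nbrs, np.arange(n)[:, None]], axis=1).ravel()
    A = sp.csr_matrix((np.ones(rows.size, dtype=np.int32), (rows, cols)), shape=(n, n))

    # symmetrized kNN edge list (u < v, unique)
    u = np.repeat(np.arange(n), k)
    v = nbrs.ravel()
    lo, hi = np.minimum(u, v), np.maximum(u, v)
    edges = np.unique(np.stack([lo, hi], axis=1), axis=0)

    inter = np.asarray(A[edges[:, 0]].multiply(A[edges[:, 1]]).sum(axis=1)).ravel()
    union = 2 * (k + 1) - inter
    weights = inter / union

    keep = weights > 0
    return CellGraph(n=n, edges=edges[keep], weights=weights[keep], k=k)


def leiden_partitions(
    graph: CellGraph,
    resolutions: list[float] | None = None,
    seed: int = 0,
) -> list[ClusteringRun]:
    """Run Leiden once per resolution on the SNN graph.

    Uses resolution-parameterized modularity (RBConfiguration) as the
    quality function.  Cluster labels are relabelled to 1..d in order of
    first appearance; identical seeds give identical partitions.
    """
    if resolutions is None:
        resolutions = default_resolutions()
    if len(resolutions) == 0:
        raise ValueError("resolution list must be non-empty")
    if any(r <= 0 for r in resolutions):
        raise ValueError("resolutions must be positive")
    g = ig.Graph(n=graph.n, edges=[tuple(e) for e in graph.edges])
    g.es["weight"] = list(graph.weights)
    runs: list[ClusteringRun] = []
    for res in resolutions:
        part = leidenalg.find_partition(
            g,
            leidenalg.RBConfigurationVertexPartition,
            weights="weight",
            resolution_parameter=float(res),
            seed=int(seed),
        )
        membership = np.asarray(part.membership)
        _, labels = np.unique(membership, return_inverse=True)
        labels = labels + 1
        runs.append(
            ClusteringRun(
                resolution=float(res),
                labels=labels,
                n_clusters=int(labels.max()),
            )
        )
    return runs
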