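"""Gene-to-centroid distance ranks and the log-ratio variability statistic.

For each clustering run the centroid of every cell cluster is computed in
the shared biplot space, genes are ranked by Euclidean distance to each
centroid (rank 1 = closest), and each gene's variability is summarized as

    v = ln( max rank / min rank )

across clusters.  A gene sitting right next to one cluster (tiny min rank)
but far from another (huge max rank) scores high; genes uniformly close or
uniformly far score near zero.  Over several Leiden runs the per-run values
are summed into the aggregated statistic used for selection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "RankProfile",
    "centroids",
    "gene_cluster_distances",
    "rank_distances",
    "log_ratio",
    "profile_run",
    "aggregate_runs",
    "select_top",
]


@dataclass
class RankProfile:
    """Rank matrix and per-run log-ratio statistic for one clustering run."""

    ranks: np.ndarray  # (p, d) ints; each column a permutation of 1..p
    v: np.ndarray      # (p,) per-gene ln(max rank / min rank)


def centroids(Phi: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Mean coordinates of the cells in each cluster.

    ``labels`` are integers in 1..d; row ``i`` of the result is the centroid
    of cluster ``i + 1``.
    """
    Phi = np.asarray(Phi, dtype=float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    expected = np.arange(1, uniq.size + 1)
    if not np.array_equal(uniq, expected):
        raise ValueError("labels must cover 1..d with no empty cluster")
    d = uniq.size
    out = np.empty((d, Phi.shape[1]))
    for i, lab in enumerate(expected):
        mask = labels == lab
        out[i] = Phi[mask].mean(axis=0)
    return out


def gene_cluster_distances(Gplus: np.ndarray, cents: np.ndarray) -> np.ndarray:
    """Euclidean distances between every gene "+" point and every centroid."""
    Gplus = np.asarray(Gplus, dtype=float)
    cents = np.asarray(cents, dtype=float)
    if Gplus.shape[1] != cents.shape[1]:
        raise ValueError(
            f"dimension mismatch: genes are {Gplus.shape[1]}-d, centroids {cents.shape[1]}-d"
        )
    return cdist(Gplus, cents)


def rank_distances(distances: np.ndarray) -> np.ndarray:
    """Rank genes by distance within each cluster column (1 = closest).

    Ties are broken by gene index so every column is a strict permutation
    of 1..p, as the null model requires.
    """
    distances = np.asarray(distances, dtype=float)
    p, d = distances.shape
    ranks = np.empty((p, d), dtype=np.int64)
    gene_idx = np.arange(p)
    for col in range(d):
        order = np.lexsort((gene_idx, distances[:, col]))
        ranks[order, col] = np.arange(1, p + 1)
    return ranks


def log_ratio(ranks: np.ndarray) -> np.ndarray:
    """Per-gene natural-log ratio of maximum to minimum distance rank."""
    ranks = np.asarray(ranks)
    if ranks.ndim != 2 or ranks.shape[1] < 2:
        raise ValueError("log-ratio undefined for a single cluster")
    return np.log(ranks.max(axis=1) / ranks.min(axis=1))


def profile_run(Phi: np.ndarray, Gplus: np.ndarray, labels: np.ndarray) -> RankProfile:
    """Centroids, distances, ranks and log-ratio for one clustering run."""
    cents = centroids(Phi, labels)
    dist = gene_cluster_distances(Gplus, cents)
    ranks = rank_distances(dist)
    return RankProfile(ranks=ranks, v=log_ratio(ranks))


def aggregate_runs(profiles: list[RankProfile]) -> np.ndarray:
    """Aggregated statistic: per-gene sum of the per-run log-ratios."""
    if len(profiles) == 0:
        raise ValueError("need at least one run to aggregate")
    return np.sum([prof.v for prof in profiles], axis=0)


def select_top(v_agg: np.ndarray, gamma: int) -> np.ndarray:
    """Indices of the gamma genes with the largest aggregated statistic.

    Boundary ties are broken by gene index (smaller index first); exactly
    ``gamma`` indices are returned, sorted by descending statistic.
    """
    v_agg = np.asarray(v_agg, dtype=float)
    p = v_agg.size
    if gamma <= 0 or gamma > p:
        raise ValueError(f"gamma must be in 1..{p}, got {gamma}")
    order = np.lexsort((np.arange(p), -v_agg))
    return order[:gamma]
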