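"""Evaluation metrics for selected gene sets and downstream clusterings.

Gene-set metrics compare a selected set against a ground-truth set (Jaccard
similarity, and recall/precision/F1 against a minority-population truth).
Clustering metrics (purity, adjusted Rand index, normalized mutual
information, silhouette, neighbourhood hit) score a predicted partition
against true labels, optionally in a provided embedding.  A small harness
reproduces the standard downstream pipeline: PCA to 15 components on the
selected-gene submatrix followed by k-means.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import (
    adjusted_rand_score,
    normalized_mutual_info_score,
    silhouette_score,
)
from sklearn.metrics.cluster import contingency_matrix
from sklearn.neighbors import NearestNeighbors

logger = logging.getLogger(__name__)

__all__ = [
    "EvaluationReport",
    "jaccard",
    "minority_f1",
    "clustering_metrics",
    "downstream_cluster",
]


@dataclass
class EvaluationReport:
    """Container for the metric values of one evaluation."""

    jaccard: float | None = None
    precision: float | None = None
    recall: float | None = None
    f1: float | None = None
    purity: float | None = None
    ari: float | None = None
    nmi: float | None = None
    silhouette: float | None = None
    neighborhood_hit: float | None = None
    parameters: dict = field(default_factory=dict)


def jaccard(A: set, B: set) -> float:
    """Jaccard similarity |A n B| / |A u B| of two gene sets."""
    A, B = set(A), set(B)
    if not A and not B:
        raise ValueError("Jaccard similarity undefined for two empty sets")
    return len(A & B) / len(A | B)


def minority_f1(truth_minority: set, selected: set) -> tuple[float, float, float]:
    """(recall, precision, F1) of a selection against a minority truth set.

    Recall = |A n B| / |A|, precision = |A n B| / |B|, F1 their harmonic
    mean (0 when both are 0).  An empty selection yields (0, 0, 0) with a
    warning rather than an error.
    """
    A, B = set(truth_minority), set(selected)
    if not A:
        raise ValueError("minority truth set must be non-empty")
    if not B:
        logger.warning("empty selection: minority F1 is 0")
        return 0.0, 0.0, 0.0
    inter = len(A & B)
    recall = inter / len(A)
    precision = inter / len(B)
    f1 = 0.0 if (precision + recall) == 0 else 2 * precision * recall / (precision + recall)
    return recall, precision, f1


def _purity(labels_true: np.ndarray, labels_pred: np.ndarray) -> float:
    cont = contingency_matrix(labels_true, labels_pred)
    return float(cont.max(axis=0).sum() / cont.sum())


def _neighborhood_hit(embedding: np.ndarray, labels: np.ndarray, k: int) -> float:
    nn = NearestNeighbors(n_neighbors=k + 1).fit(embedding)
    _, idx = nn.kneighbors(embedding)
    neigh_labels = labels[idx[:, 1:]]  # drop the point itself
    return float(np.mean(neigh_labels == labels[:, None]))


def clustering_metrics(
    labels_true: np.ndarray,
    labels_pred: np.ndarray,
    embedding: np.ndarray | None = None,
    k_neighbors: int = 30,
) -> EvaluationReport:
    """Purity, ARI, NMI and (if an embedding is given) silhouette and
    neighbourhood hit.

    Neighbourhood hit is the mean fraction of each point's ``k_neighbors``
    Euclidean nearest neighbours in the embedding sharing its true label
    (default 30 neighbours).  NMI uses the 2 I / (H + H) normalization and
    is reported as 0 with a warning when either labelling has one cluster.
    """
    labels_true = np.asarray(labels_true)
    labels_pred = np.asarray(labels_pred)
    if labels_true.shape != labels_pred.shape:
        raise ValueError("label vectors must have equal length")
    report = EvaluationReport(parameters={"k_neighbors": k_neighbors})
    report.purity = _purity(labels_true, labels_pred)
    report.ari = float(adjusted_rand_score(labels_true, labels_pred))
    if len(np.unique(labels_true)) < 2 or len(np.unique(labels_pred)) < 2:
        logger.warning("single-cluster labelling: NMI reported as 0")
        report.nmi = 0.0
    else:
        report.nmi = float(normalized_mutual_info_score(labels_true, labels_pred))
    if embedding is not None:
        embedding = np.asarray(embedding, dtype=float)
        if embedding.shape[0] != labels_true.size:
            raise ValueError("embedding rows must match labels")
        if len(np.unique(labels_pred)) >= 2:
            report.silhouette = float(silhouette_score(embedding, labels_pred))
        k = min(k_neighbors, embedding.shape[0] - 1)
        report.neighborhood_hit = _neighborhood_hit(embedding, labels_true, k)
    return report


def downstream_cluster(
    counts: np.ndarray,
    n_clusters: int,
    seed: int = 0,
    n_components: int = 15,
) -> np.ndarray:
    """PCA (15 components by default) then k-means on a gene-subset matrix.

    ``counts`` is the cell x selected-gene raw count matrix; PCA centers
    each gene internally.  Used only by the evaluation harness.
    """
    counts = np.asarray(counts, dtype=float)
    n = counts.shape[0]
    if n_clusters > n:
        raise ValueError(f"n_clusters={n_clusters} exceeds the {n} cells")
    n_components = max(1, min(n_components, min(counts.shape) - 1))
    if n_clusters == n:
        return np.arange(1, n + 1)
    pcs = PCA(n_components=n_components, random_state=seed).fit_transform(counts)
    km = KMeans(n_clusters=n_clusters, random_state=seed, n_init=10).fit(pcs)
    return km.labels_ + 1
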