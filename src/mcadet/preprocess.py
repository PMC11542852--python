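"""Fuzzy coding of raw counts and construction of the correspondence model.

The first stage of the pipeline treats each gene as a categorical variable
with two fuzzy categories, "presence" (+) and "absence" (-).  Raw counts are
mapped linearly onto [0, 1] between the per-gene minimum and maximum (the
hinge points), doubling an ``n x p`` count matrix into an ``n x 2p`` fuzzy
matrix ``Z``.  Rescaling ``Z`` to unit grand total gives the correspondence
matrix ``P`` whose margins (row and column masses) define the standardized
Pearson residuals that the MCA stage decomposes.

No normalization or log transform is applied: the linear fuzzy map already
puts every gene on a common [0, 1] scale regardless of its expression
magnitude, which is the point of the coding.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

logger = logging.getLogger(__name__)

__all__ = [
    "CountMatrix",
    "CorrespondenceModel",
    "ResidualMatrix",
    "drop_degenerate_genes",
    "fuzzy_code",
    "build_correspondence",
    "pearson_residuals",
]


@dataclass
class CountMatrix:
    """Raw cell x gene expression matrix of non-negative integers.

    Parameters
    ----------
    values
        ``(n_cells, n_genes)`` array (dense or scipy sparse) of counts.
    gene_ids, cell_ids
        Unique string identifiers for columns and rows respectively.
    """

    values: np.ndarray | sp.spmatrix
    gene_ids: list[str]
    cell_ids: list[str]

    def __post_init__(self) -> None:
        if sp.issparse(self.values):
            self.values = self.values.tocsc()
            data = self.values.data
        else:
            self.values = np.asarray(self.values)
            data = self.values
        if self.values.ndim != 2:
            raise ValueError("count matrix must be two-dimensional")
        n, p = self.values.shape
        if n < 2 or p < 2:
            raise ValueError(f"need at least 2 cells and 2 genes, got {n} x {p}")
        if len(self.gene_ids) != p:
            raise ValueError("gene_ids length does not match number of columns")
        if len(self.cell_ids) != n:
            raise ValueError("cell_ids length does not match number of rows")
        if len(set(self.gene_ids)) != p:
            raise ValueError("gene_ids are not unique")
        if len(set(self.cell_ids)) != n:
            raise ValueError("cell_ids are not unique")
        if data.size and (np.min(data) < 0):
            raise ValueError("counts must be non-negative")
        if data.size and not np.all(np.equal(np.mod(data, 1), 0)):
            raise ValueError("counts must be integer-valued")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def dense(self) -> np.ndarray:
        """Counts as a dense float array (copies sparse input)."""
        if sp.issparse(self.values):
            return np.asarray(self.values.todense(), dtype=float)
        return np.asarray(self.values, dtype=float)


@dataclass
class CorrespondenceModel:
    """Fuzzy-coded matrix ``Z``, correspondence matrix ``P`` and margins.

    Columns are interleaved as (gene1+, gene1-, gene2+, gene2-, ...): the
    "+" categories sit at even indices, which downstream code relies on.
    """

    Z: np.ndarray           # (n, 2p), entries in [0, 1]
    P: np.ndarray           # (n, 2p), grand sum 1
    row_mass: np.ndarray    # (n,), each 1/n
    col_mass: np.ndarray    # (2p,), sums to 1
    hinge_lo: np.ndarray    # (p,) per-gene minimum count
    hinge_hi: np.ndarray    # (p,) per-gene maximum count
    gene_ids: list[str] = field(default_factory=list)
    cell_ids: list[str] = field(default_factory=list)

    @property
    def n_cells(self) -> int:
        return self.Z.shape[0]

    @property
    def n_genes(self) -> int:
        return self.Z.shape[1] // 2


@dataclass
class ResidualMatrix:
    """Standardized Pearson residuals ``R = D_r^{-1/2} (P - r c^T) D_c^{-1/2}``."""

    R: np.ndarray  # (n, 2p)


def _column_min_max(values: np.ndarray | sp.spmatrix) -> tuple[np.ndarray, np.ndarray]:
    if sp.issparse(values):
        m1 = np.asarray(values.min(axis=0).todense()).ravel()
        m2 = np.asarray(values.max(axis=0).todense()).ravel()
    else:
        m1 = np.min(values, axis=0)
        m2 = np.max(values, axis=0)
    return np.asarray(m1, dtype=float), np.asarray(m2, dtype=float)


def drop_degenerate_genes(counts: CountMatrix) -> CountMatrix:
    """Remove genes whose count is constant across all cells.

    The fuzzy coding divides by ``max - min`` per gene, so constant columns
    (including all-zero genes) are undefined under the coding and carry no
    variability; they are dropped with a log record of the removed ids.
    """
    m1, m2 = _column_min_max(counts.values)
    keep = m2 > m1
    if not np.any(keep):
        raise ValueError("no usable genes: every gene is constant across cells")
    if np.all(keep):
        return counts
    dropped = [g for g, k in zip(counts.gene_ids, keep) if not k]
    logger.info("dropping %d constant gene(s): %s", len(dropped), ", ".join(dropped[:20]))
    values = counts.values[:, np.flatnonzero(keep)] if sp.issparse(counts.values) else counts.values[:, keep]
    return CountMatrix(
        values=values,
        gene_ids=[g for g, k in zip(counts.gene_ids, keep) if k],
        cell_ids=list(counts.cell_ids),
    )


def fuzzy_code(counts: CountMatrix) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Double the count matrix into fuzzy presence/absence memberships.

    For gene ``j`` with hinge points ``m1`` (min) and ``m2`` (max)::

        Z+ = (Y - m1) / (m2 - m1),    Z- = 1 - Z+

    Returns
    -------
    Z : (n, 2p) array with (+, -) column pairs interleaved
    hinge_lo, hinge_hi : per-gene hinge points
    """
    m1, m2 = _column_min_max(counts.values)
    span = m2 - m1
    bad = span <= 0
    if np.any(bad):
        name = counts.gene_ids[int(np.flatnonzero(bad)[0])]
        raise ValueError(
            f"gene {name!r} is constant across cells; fuzzy coding would divide "
            "by zero (run drop_degenerate_genes first)"
        )
    Y = counts.dense()
    plus = (Y - m1) / span
    n, p = Y.shape
    Z = np.empty((n, 2 * p), dtype=float)
    Z[:, 0::2] = plus
    Z[:, 1::2] = 1.0 - plus
    return Z, m1, m2


def build_correspondence(
    Z: np.ndarray,
    hinge_lo: np.ndarray | None = None,
    hinge_hi: np.ndarray | None = None,
    gene_ids: list[str] | None = None,
    cell_ids: list[str] | None = None,
) -> CorrespondenceModel:
    """Rescale the fuzzy matrix to a correspondence matrix with its margins.

    ``P = Z / (n p)`` has grand total 1.  Because each (+, -) pair sums to 1,
    every row mass is exactly ``1/n``; column masses are the column sums of P.
    """
    n, two_p = Z.shape
    if two_p % 2 != 0:
        raise ValueError("Z must have an even number of columns (doubled genes)")
    p = two_p // 2
    P = Z / (n * p)
    row_mass = P.sum(axis=1)
    col_mass = P.sum(axis=0)
    if np.any(col_mass <= 0):
        j = int(np.flatnonzero(col_mass <= 0)[0])
        raise ValueError(f"column {j} of the fuzzy matrix has zero mass")
    return CorrespondenceModel(
        Z=Z,
        P=P,
        row_mass=row_mass,
        col_mass=col_mass,
        hinge_lo=np.asarray(hinge_lo) if hinge_lo is not None else np.zeros(p),
        hinge_hi=np.asarray(hinge_hi) if hinge_hi is not None else np.ones(p),
        gene_ids=list(gene_ids) if gene_ids is not None else [f"g{j}" for j in range(p)],
        cell_ids=list(cell_ids) if cell_ids is not None else [f"c{i}" for i in range(n)],
    )


def preprocess_counts(counts: CountMatrix) -> CorrespondenceModel:
    """Convenience wrapper: drop constant genes, fuzzy-code, build the model."""
    counts = drop_degenerate_genes(counts)
    Z, m1, m2 = fuzzy_code(counts)
    return build_correspondence(Z, m1, m2, counts.gene_ids, counts.cell_ids)


def pearson_residuals(model: CorrespondenceModel) -> ResidualMatrix:
    """Standardized Pearson residuals of P against the independence model.

    Elementwise ``(P_ij - r_i c_j) / sqrt(r_i c_j)``.
    """
    r = model.row_mass
    c = model.col_mass
    if np.any(r <= 0) or np.any(c <= 0):
        raise ValueError("all row and column masses must be strictly positive")
    expected = np.outer(r, c)
    R = (model.P - expected) / np.sqrt(expected)
    return ResidualMatrix(R=R)
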