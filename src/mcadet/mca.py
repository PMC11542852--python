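"""Truncated SVD of the residual matrix and biplot coordinates.

The standardized Pearson residual matrix ``R`` is decomposed as
``R = U diag(lambda) V^T``.  Cells receive *standard* row coordinates
``Phi = D_r^{-1/2} U`` and gene categories receive *principal* column
coordinates ``G = D_c^{-1/2} V diag(lambda)``.  This column-principal
asymmetric pairing supports a distance interpretation: proximity of a gene
"+" category to a cell (or cell-cluster centroid) in the shared space
indicates association.  Only the "+" category coordinates are kept for
downstream distance ranking; the "-" category of each gene is collinear
with it through the origin (their mass-weighted average is the origin).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.sparse.linalg

from .preprocess import CorrespondenceModel, ResidualMatrix

__all__ = ["MCAEmbedding", "decompose", "export_biplot_coordinates"]

#: below this size a full (exact) SVD is used instead of an iterative one
_FULL_SVD_LIMIT = 400


@dataclass
class MCAEmbedding:
    """Truncated SVD factors and derived biplot coordinates."""

    U: np.ndarray                # (n, K)
    singular_values: np.ndarray  # (K,), non-increasing
    V: np.ndarray                # (2p, K)
    Phi: np.ndarray              # (n, K) standard row coordinates of cells
    Gplus: np.ndarray            # (p, K) principal coordinates of "+" categories
    G: np.ndarray                # (2p, K) full principal column coordinates
    K: int
    gene_ids: list[str]
    cell_ids: list[str]


def decompose(
    residuals: ResidualMatrix,
    model: CorrespondenceModel,
    K: int = 60,
    seed: int = 0,
) -> MCAEmbedding:
    """Truncated SVD of R and construction of the biplot coordinates.

    Parameters
    ----------
    K
        Number of components retained (default 60).  Must satisfy
        ``K <= min(n, 2p) - 1``.
    seed
        Seeds the starting vector of the iterative solver so repeated runs
        give identical factors.  Small problems use an exact full SVD.

    Notes
    -----
    The sign of each component is fixed so that the entry of largest
    magnitude in the corresponding right singular vector is positive; all
    downstream quantities (distances, ranks) are invariant to this choice.
    """
    R = residuals.R
    n, two_p = R.shape
    kmax = min(n, two_p) - 1
    if K < 1 or K > kmax:
        raise ValueError(f"K must be in [1, {kmax}] for a {n} x {two_p} matrix, got {K}")

    if min(n, two_p) <= _FULL_SVD_LIMIT:
        U, s, Vt = scipy.linalg.svd(R, full_matrices=False)
        U, s, Vt = U[:, :K], s[:K], Vt[:K]
    else:
        rng = np.random.default_rng(seed)
        v0 = rng.standard_normal(min(n, two_p))
        try:
            U, s, Vt = scipy.sparse.linalg.svds(R, k=K, v0=v0)
        except Exception as exc:  # pragma: no cover - solver failure path
            raise RuntimeError(
                "truncated SVD did not converge; retry with a different seed "
                "or a smaller K"
            ) from exc
        order = np.argsort(s)[::-1]
        U, s, Vt = U[:, order], s[order], Vt[order]
    V = Vt.T

    # deterministic sign convention
    for k in range(V.shape[1]):
        j = int(np.argmax(np.abs(V[:, k])))
        if V[j, k] < 0:
            V[:, k] = -V[:, k]
            U[:, k] = -U[:, k]

    Phi = U / np.sqrt(model.row_mass)[:, None]
    G = (V / np.sqrt(model.col_mass)[:, None]) * s[None, :]
    Gplus = G[0::2]
    return MCAEmbedding(
        U=U,
        singular_values=s,
        V=V,
        Phi=Phi,
        Gplus=Gplus,
        G=G,
        K=K,
        gene_ids=list(model.gene_ids),
        cell_ids=list(model.cell_ids),
    )


def reconstitute(emb: MCAEmbedding, model: CorrespondenceModel) -> np.ndarray:
    """Rebuild P from the embedding via the column-principal form.

    ``P ~= D_r (1_n 1_{2p}^T + Phi G^T) D_c``; exact when K equals the rank
    of the residual matrix.
    """
    n, two_p = model.P.shape
    ones = np.ones((n, two_p))
    inner = ones + emb.Phi @ emb.G.T
    return inner * np.outer(model.row_mass, model.col_mass)


def export_biplot_coordinates(emb: MCAEmbedding, dims: tuple[int, int] = (1, 2)) -> pd.DataFrame:
    """Long-format table of cell and gene "+" coordinates on two components.

    ``dims`` are 1-based component indices.  Output columns:
    ``id``, ``kind`` (cell/gene), ``dim_a``, ``dim_b``.
    """
    a, b = dims
    if not (1 <= a <= emb.K and 1 <= b <= emb.K):
        raise ValueError(f"dims must be within 1..{emb.K}, got {dims}")
    cells = pd.DataFrame(
        {
            "id": emb.cell_ids,
            "kind": "cell",
            "dim_a": emb.Phi[:, a - 1],
            "dim_b": emb.Phi[:, b - 1],
        }
    )
    genes = pd.DataFrame(
        {
            "id": emb.gene_ids,
            "kind": "gene",
            "dim_a": emb.Gplus[:, a - 1],
            "dim_b": emb.Gplus[:, b - 1],
        }
    )
    return pd.concat([cells, genes], ignore_index=True)
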