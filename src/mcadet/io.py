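"""Readers and writers for count matrices, gene lists and selection tables."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .null_test import SelectionResult
from .preprocess import CountMatrix

__all__ = ["read_counts", "read_gene_list", "write_selection", "read_selection"]


def _read_sidecar(path: Path) -> list[str]:
    # first whitespace-separated field of each line (10x gene files may
    # carry a second symbol column)
    out = []
    for line in path.read_text().splitlines():
        line = line.strip()
        if line:
            out.append(line.split("\t")[0].split()[0])
    return out


def _read_mtx_triplet(mtx_path: Path) -> CountMatrix:
    d = mtx_path.parent
    genes_path = d / "genes.tsv"
    if not genes_path.exists():
        genes_path = d / "features.tsv"
    barcodes_path = d / "barcodes.tsv"
    for pth in (genes_path, barcodes_path):
        if not pth.exists():
            raise FileNotFoundError(f"missing sidecar file {pth}")
    genes = _read_sidecar(genes_path)
    barcodes = _read_sidecar(barcodes_path)
    mat = scipy.io.mmread(mtx_path).tocsc()
    if mat.shape == (len(genes), len(barcodes)):
        mat = mat.T.tocsc()  # 10x convention is genes x cells
    elif mat.shape != (len(barcodes), len(genes)):
        raise ValueError(
            f"matrix shape {mat.shape} matches neither (cells={len(barcodes)}, "
            f"genes={len(genes)}) nor its transpose"
        )
    return CountMatrix(values=mat, gene_ids=genes, cell_ids=barcodes)


def _read_dense(path: Path) -> CountMatrix:
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    values = df.to_numpy()
    bad = (values < 0) | (np.mod(values, 1) != 0)
    if np.any(bad):
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"non-integer or negative entry at cell {df.index[i]!r}, gene {df.columns[j]!r}"
        )
    return CountMatrix(
        values=values.astype(np.int64),
        gene_ids=[str(g) for g in df.columns],
        cell_ids=[str(c) for c in df.index],
    )


def read_counts(path: str | Path) -> CountMatrix:
    """Read a count matrix into cell x gene orientation.

    Supports Matrix Market (``.mtx`` with ``genes.tsv``/``features.tsv`` and
    ``barcodes.tsv`` sidecars in the same directory; orientation detected
    from the sidecar lengths) and dense TSV/CSV with a header row of gene
    ids and a first column of cell ids.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".mtx":
        return _read_mtx_triplet(path)
    return _read_dense(path)


def read_gene_list(path: str | Path) -> set[str]:
    """Plain-text gene list, one id per line."""
    return {line.strip() for line in Path(path).read_text().splitlines() if line.strip()}


def write_selection(result: SelectionResult, path: str | Path) -> None:
    """Write the per-gene selection table as TSV.

    Columns: ``gene_id  v_agg  p_value  q_value  selected``; rows ordered by
    descending statistic then gene id; filtered genes have a literal ``NA``
    q-value.
    """
    df = selection_frame(result)
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def selection_frame(result: SelectionResult) -> pd.DataFrame:
    """Selection result as a DataFrame (same ordering as the TSV output)."""
    df = pd.DataFrame(
        {
            "gene_id": result.gene_ids,
            "v_agg": result.v_agg,
            "p_value": result.p_values,
            "q_value": result.q_values,
            "selected": result.selected,
        }
    )
    return df.sort_values(["v_agg", "gene_id"], ascending=[False, True], ignore_index=True)


def read_selection(path: str | Path) -> pd.DataFrame:
    """Round-trip reader for the selection TSV."""
    return pd.read_csv(path, sep="\t", na_values=["NA"])
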