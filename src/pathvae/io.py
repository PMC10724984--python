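"""Readers and writers for the package's on-disk formats.

Fixture directories hold Matrix Market counts with TSV sidecars and a GMT
file; dense delimited matrices (cells x genes with header row and index
column) are supported as an alternative input; embeddings, metric reports
and rankings are delimited tables.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
from anndata import AnnData

__all__ = [
    "load_fixture",
    "read_counts_mtx",
    "read_counts_dense",
    "write_counts_dense",
    "write_embedding",
    "read_embedding",
]


def read_counts_mtx(
    matrix_path: str | Path,
    cells_path: str | Path,
    genes_path: str | Path,
) -> AnnData:
    """Assemble an AnnData from a Matrix Market counts file (cells x genes)
    plus cell and gene TSV sidecars."""
    X = sp.csr_matrix(scipy.io.mmread(str(matrix_path))).astype(np.float64)
    cells = pd.read_csv(cells_path, sep="\t", index_col=0, dtype=str)
    genes = pd.read_csv(genes_path, sep="\t", dtype=str)
    gene_index = pd.Index(genes.iloc[:, 0], name="gene")
    if X.shape != (len(cells), len(gene_index)):
        raise ValueError(
            f"matrix shape {X.shape} does not match metadata "
            f"({len(cells)} cells, {len(gene_index)} genes)"
        )
    adata = AnnData(X=X, obs=cells, var=pd.DataFrame(index=gene_index))
    adata.layers["counts"] = adata.X.copy()
    return adata


def load_fixture(directory: str | Path) -> AnnData:
    """Read a fixture directory written by :func:`synthetic.write_fixture`."""
    directory = Path(directory)
    return read_counts_mtx(
        directory / "matrix.mtx",
        directory / "cells.tsv",
        directory / "genes.tsv",
    )


def read_counts_dense(path: str | Path, sep: str = "\t") -> AnnData:
    """Read a dense delimited matrix: header row = genes, first column =
    cell ids."""
    df = pd.read_csv(path, sep=sep, index_col=0)
    adata = AnnData(
        X=df.to_numpy(dtype=np.float64),
        obs=pd.DataFrame(index=df.index.astype(str)),
        var=pd.DataFrame(index=df.columns.astype(str)),
    )
    adata.layers["counts"] = adata.X.copy()
    return adata


def write_counts_dense(adata: AnnData, path: str | Path, sep: str = "\t") -> None:
    X = adata.X.toarray() if sp.issparse(adata.X) else np.asarray(adata.X)
    pd.DataFrame(X, index=adata.obs_names, columns=adata.var_names).to_csv(
        path, sep=sep
    )


def write_embedding(embedding: pd.DataFrame, path: str | Path) -> None:
    """Cells x pathways table, tab-separated, with header and cell index."""
    embedding.rename_axis("cell_id").to_csv(path, sep="\t")


def read_embedding(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)
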