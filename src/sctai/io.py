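"""Readers and writers for the on-disk exchange formats.

Count matrices travel as a MatrixMarket trio (matrix.mtx with genes as rows
and cells as columns, the 10x/CellRanger orientation, plus genes.tsv and
barcodes.tsv), cell annotations and all result tables as TSV.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData
from scipy.io import mmread, mmwrite

__all__ = ["read_mtx_dir", "write_mtx_dir", "read_annotation", "attach_annotation"]


def read_mtx_dir(
    path: str | Path,
    matrix: str = "matrix.mtx",
    genes: str = "genes.tsv",
    barcodes: str = "barcodes.tsv",
) -> AnnData:
    """Load a genes x cells MatrixMarket trio into AnnData (cells x genes)."""
    path = Path(path)
    X = sp.csr_matrix(mmread(path / matrix).T)
    gene_ids = pd.read_csv(path / genes, sep="\t", header=None)[0].astype(str)
    cell_ids = pd.read_csv(path / barcodes, sep="\t", header=None)[0].astype(str)
    if X.shape != (len(cell_ids), len(gene_ids)):
        raise ValueError(
            f"matrix shape {X.shape} inconsistent with {len(cell_ids)} barcodes x "
            f"{len(gene_ids)} genes"
        )
    if gene_ids.duplicated().any() or cell_ids.duplicated().any():
        raise ValueError("gene and cell ids must be unique")
    return AnnData(
        X=X,
        obs=pd.DataFrame(index=cell_ids.values),
        var=pd.DataFrame(index=gene_ids.values),
    )


def write_mtx_dir(
    adata: AnnData,
    path: str | Path,
    matrix: str = "matrix.mtx",
    genes: str = "genes.tsv",
    barcodes: str = "barcodes.tsv",
) -> None:
    """Write AnnData to a genes x cells MatrixMarket trio."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    X = adata.X
    X = sp.coo_matrix(X.T) if sp.issparse(X) else sp.coo_matrix(np.asarray(X).T)
    mmwrite(path / matrix, X)
    pd.Series(adata.var_names).to_csv(path / genes, sep="\t", header=False, index=False)
    pd.Series(adata.obs_names).to_csv(path / barcodes, sep="\t", header=False, index=False)


def read_annotation(path: str | Path) -> pd.DataFrame:
    """Read a cell annotation TSV: cell_id, cell_type[, mito_fraction]."""
    ann = pd.read_csv(path, sep="\t", dtype={"cell_id": str, "cell_type": str})
    return ann.set_index("cell_id")


def attach_annotation(adata: AnnData, annotation: pd.DataFrame) -> AnnData:
    """Join a cell annotation table onto ``obs``; every cell must be covered."""
    missing = adata.obs_names.difference(annotation.index)
    if len(missing):
        raise ValueError(f"annotation missing for cells: {missing[:5].tolist()}")
    for col in annotation.columns:
        adata.obs[col] = annotation.loc[adata.obs_names, col].values
    return adata
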