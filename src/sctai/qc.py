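"""Single-cell QC filters, total-count normalization, and downsampling.

Operates on :class:`anndata.AnnData` with cells in ``obs`` and genes in
``var``; ``obs["cell_type"]`` carries the (precomputed) cell labels and raw
counts go in ``X``.  The standard matrix operations are delegated to scanpy;
this module pins down the boundary conventions, which matter: cells are
retained with ``min_genes <= n_genes_detected <= max_genes`` and
``mito_fraction <= max_mito``; genes are retained when detected
(count > 0) in at least ``min_cells`` cells.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData

__all__ = [
    "annotate_qc_metrics",
    "filter_cells",
    "filter_genes",
    "normalize_total",
    "downsample_cells",
]


def _sum(X, axis: int) -> np.ndarray:
    if sp.issparse(X):
        return np.asarray(X.sum(axis=axis)).ravel()
    return np.asarray(np.asarray(X).sum(axis=axis)).ravel()


def _ndetected(X, axis: int) -> np.ndarray:
    if sp.issparse(X):
        return np.asarray((X > 0).sum(axis=axis)).ravel()
    return (np.asarray(X) > 0).sum(axis=axis)


def annotate_qc_metrics(adata: AnnData, mito_prefix: str = "mt-") -> AnnData:
    """Add ``n_genes_detected`` and ``mito_fraction`` to ``obs`` in place.

    ``mito_fraction`` is kept if already present (e.g. supplied with the
    annotation table); otherwise it is computed as the fraction of counts on
    genes whose id starts with ``mito_prefix`` (case-insensitive).
    """
    adata.obs["n_genes_detected"] = _ndetected(adata.X, axis=1).astype(int)
    if "mito_fraction" in adata.obs:
        frac = adata.obs["mito_fraction"].to_numpy(float)
        if np.any((frac < 0) | (frac > 1) | ~np.isfinite(frac)):
            raise ValueError("mito_fraction must lie in [0, 1]")
        return adata

    import scanpy as sc

    adata.var["mt"] = adata.var_names.str.lower().str.startswith(mito_prefix.lower())
    sc.pp.calculate_qc_metrics(
        adata, qc_vars=["mt"], percent_top=None, log1p=False, inplace=True
    )
    adata.obs["mito_fraction"] = adata.obs["pct_counts_mt"].to_numpy(float) / 100.0
    return adata


def filter_cells(
    adata: AnnData,
    min_genes: int = 200,
    max_genes: int = 5000,
    max_mito: float = 0.20,
    mito_prefix: str = "mt-",
) -> AnnData:
    """Retain cells with min_genes <= detected genes <= max_genes and
    mitochondrial read fraction <= max_mito.  Cell order is preserved."""
    if not (0 <= min_genes < max_genes):
        raise ValueError("thresholds must satisfy 0 <= min_genes < max_genes")
    if not (0 <= max_mito <= 1):
        raise ValueError("max_mito must lie in [0, 1]")
    if adata.obs.index.isna().any():
        raise ValueError("every cell must be annotated")
    adata = annotate_qc_metrics(adata.copy(), mito_prefix=mito_prefix)
    n = adata.obs["n_genes_detected"].to_numpy()
    mito = adata.obs["mito_fraction"].to_numpy(float)
    keep = (n >= min_genes) & (n <= max_genes) & (mito <= max_mito)
    return adata[keep].copy()


def filter_genes(adata: AnnData, min_cells: int = 10) -> AnnData:
    """Retain genes detected (count > 0) in at least ``min_cells`` cells;
    all-zero genes are removed by the same rule."""
    if min_cells < 1:
        raise ValueError("min_cells must be >= 1")
    import scanpy as sc

    adata = adata.copy()
    sc.pp.filter_genes(adata, min_cells=min_cells)
    return adata


def normalize_total(adata: AnnData, scale_factor: float = 1e6) -> AnnData:
    """Per-cell total-count normalization: e_ic = raw_ic / colsum_c * scale.

    Every cell's normalized counts sum to ``scale_factor``.  Raw counts are
    preserved in ``layers["counts"]``.  Cells with zero total counts are an
    error (they should have been removed by :func:`filter_cells`).
    """
    if scale_factor <= 0:
        raise ValueError("scale_factor must be > 0")
    totals = _sum(adata.X, axis=1)
    if np.any(totals == 0):
        bad = adata.obs_names[totals == 0].tolist()
        raise ValueError(f"cells with zero total counts (filter first): {bad[:5]}")
    import scanpy as sc

    out = adata.copy()
    out.layers["counts"] = out.X.copy()
    out.X = out.X.astype(np.float64)
    sc.pp.normalize_total(out, target_sum=scale_factor)
    out.uns["scale_factor"] = float(scale_factor)
    return out


def downsample_cells(
    labels: pd.Series | np.ndarray, n: int, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """Sample up to ``n`` cells per cell type, uniformly without replacement.

    Types with fewer than ``n`` cells keep all their cells.  Returns sorted
    integer positions into ``labels``; reproducible for a fixed seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    labels = pd.Series(np.asarray(labels))
    picked: list[np.ndarray] = []
    for _, idx in sorted(labels.groupby(labels).groups.items(), key=lambda kv: str(kv[0])):
        pos = np.asarray(idx)
        if len(pos) > n:
            pos = rng.choice(pos, size=n, replace=False)
        picked.append(pos)
    return np.sort(np.concatenate(picked))
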