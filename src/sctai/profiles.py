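"""Per-phylostratum mean expression profiles and their min-max relative form.

The mean profile f̄(n, s) averages, over the cells of type s, the per-cell
mean normalized expression of the genes of phylostratum n (two-stage
averaging: per cell first, then across cells).  Relative expression rescales
each phylostratum row linearly so the lowest cell type sits at 0 and the
highest at 1:

    RE(n)_s = (f̄(n, s) - f̄_min) / (f̄_max - f̄_min).
"""

from __future__ import annotations

import warnings
from itertools import combinations
from typing import Mapping

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData
from scipy import stats

from .enrichment import bh_adjust
from .tai import _ages_series, _rank_sum_pair

__all__ = [
    "mean_expression_by_ps",
    "relative_expression",
    "compare_ps_expression",
    "per_cell_ps_means",
]


def per_cell_ps_means(norm: AnnData, ages) -> pd.DataFrame:
    """Mean normalized expression of each phylostratum's genes in each cell
    (cells x ps).  Phylostrata with no age-mapped genes in the matrix are
    absent from the columns."""
    ages = _ages_series(ages)
    genes = norm.var_names.intersection(ages.index)
    if len(genes) == 0:
        raise ValueError("no age-mapped genes in the matrix")
    X = norm[:, genes].X
    X = np.asarray(X.todense()) if sp.issparse(X) else np.asarray(X)
    ps = ages.loc[genes].to_numpy()
    strata = np.unique(ps)
    ind = (ps[:, None] == strata[None, :]).astype(np.float64)
    sums = X.astype(np.float64) @ ind
    means = sums / ind.sum(axis=0)[None, :]
    return pd.DataFrame(means, index=norm.obs_names, columns=pd.Index(strata, name="ps"))


def mean_expression_by_ps(
    norm: AnnData, ages, labels: pd.Series | np.ndarray | None = None,
    groupby: str = "cell_type",
) -> pd.DataFrame:
    """Mean expression matrix f̄: rows phylostrata, columns cell types.

    Two-stage mean: per-cell average over the ps genes, then average over
    the cells of each type.  A ps with no genes in the matrix is missing
    (absent row), not zero.
    """
    if labels is None:
        labels = norm.obs[groupby]
    labels = pd.Series(np.asarray(labels).astype(str), index=norm.obs_names)
    cell_ps = per_cell_ps_means(norm, ages)
    out = cell_ps.groupby(labels, observed=True).mean().T
    out.index.name = "ps"
    out.columns.name = "cell_type"
    return out


def relative_expression(mean_matrix: pd.DataFrame) -> pd.DataFrame:
    """Row-wise min-max rescaling of f̄ to [0, 1] across cell types.

    Degenerate (constant) rows become NaN with a warning; a single cell
    type is an error because the transform is undefined.
    """
    if mean_matrix.shape[1] < 2:
        raise ValueError("relative expression needs at least two cell types")
    vals = mean_matrix.to_numpy(float)
    lo = np.nanmin(vals, axis=1, keepdims=True)
    hi = np.nanmax(vals, axis=1, keepdims=True)
    span = hi - lo
    degenerate = (span == 0).ravel()
    if degenerate.any():
        warnings.warn(
            f"constant mean-expression rows set to NaN: ps {mean_matrix.index[degenerate].tolist()}",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        re = (vals - lo) / np.where(span == 0, np.nan, span)
    return pd.DataFrame(re, index=mean_matrix.index, columns=mean_matrix.columns)


def compare_ps_expression(
    norm: AnnData, ages, labels: pd.Series | np.ndarray | None = None,
    groupby: str = "cell_type", exact_max: int = 25,
) -> pd.DataFrame:
    """Pairwise Wilcoxon tests of per-cell ps-mean expression across types,
    one row per (ps, pair), BH-adjusted over the whole table."""
    if labels is None:
        labels = norm.obs[groupby]
    labels = pd.Series(np.asarray(labels).astype(str), index=norm.obs_names)
    counts = labels.value_counts()
    if len(counts) < 2:
        raise ValueError("need at least two cell types")
    if (counts < 2).any():
        raise ValueError(
            f"cell types with fewer than 2 cells: {counts[counts < 2].index.tolist()}"
        )
    cell_ps = per_cell_ps_means(norm, ages)
    rows = []
    for ps in cell_ps.columns:
        col = cell_ps[ps]
        for g1, g2 in combinations(sorted(counts.index), 2):
            x, y = col[labels == g1].to_numpy(), col[labels == g2].to_numpy()
            u, p = _rank_sum_pair(x, y, exact_max=exact_max)
            rows.append(
                dict(ps=int(ps), group1=g1, group2=g2, statistic=u, p=p,
                     median1=float(np.median(x)), median2=float(np.median(y)))
            )
    table = pd.DataFrame(rows)
    table["q"] = bh_adjust(table["p"].to_numpy())
    return table
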