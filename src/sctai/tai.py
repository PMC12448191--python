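"""Transcriptome age index (TAI) and its partial decomposition.

For a cell c with normalized expression e_ic over age-mapped genes i, the
TAI is the expression-weighted mean phylostratum

    TAI_c = sum_i ps_i * e_ic / sum_i e_ic ,

lower values meaning an evolutionarily older transcriptome.  The partial
TAI of phylostratum j,

    pTAI_jc = ps_j * (sum_{i in ps j} e_ic) / (sum_i e_ic) ,

is the additive contribution of age-j genes, so sum_j pTAI_jc = TAI_c.
Genes without an age assignment are excluded from both numerator and
denominator.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData
from scipy import stats

from .enrichment import bh_adjust

__all__ = ["compute_tai", "compute_partial_tai", "compare_tai", "significance_stars"]


def _ages_series(ages) -> pd.Series:
    if hasattr(ages, "ages"):  # GeneAgeMap
        ages = ages.ages
    if not isinstance(ages, pd.Series):
        ages = pd.Series(ages)
    return ages.astype(int)


def _aligned(norm: AnnData, ages, gene_subset=None):
    """Expression over age-mapped genes (dense cells x genes) and their ps."""
    ages = _ages_series(ages)
    genes = norm.var_names.intersection(ages.index)
    if gene_subset is not None:
        genes = genes.intersection(pd.Index(list(gene_subset)))
    if len(genes) == 0:
        raise ValueError("no age-mapped genes in the matrix (after subsetting)")
    X = norm[:, genes].X
    X = np.asarray(X.todense()) if sp.issparse(X) else np.asarray(X)
    return X.astype(np.float64), ages.loc[genes].to_numpy(), genes


def compute_tai(
    norm: AnnData,
    ages: pd.Series | Mapping[str, int],
    gene_subset: Iterable[str] | None = None,
) -> pd.Series:
    """Per-cell TAI over age-mapped genes, optionally restricted to a subset
    (e.g. specifically expressed genes).

    Cells whose restricted expression is all zero get NaN, not 0.
    """
    X, ps, _ = _aligned(norm, ages, gene_subset)
    denom = X.sum(axis=1)
    num = X @ ps
    with np.errstate(invalid="ignore", divide="ignore"):
        tai = np.where(denom > 0, num / np.where(denom > 0, denom, 1.0), np.nan)
    return pd.Series(tai, index=norm.obs_names, name="tai")


def compute_partial_tai(
    norm: AnnData, ages: pd.Series | Mapping[str, int]
) -> pd.DataFrame:
    """Per-cell partial TAI, one column per phylostratum present in ``ages``.

    Rows sum to the cell's TAI; all entries are nonnegative.
    """
    X, ps, _ = _aligned(norm, ages)
    denom = X.sum(axis=1)
    strata = np.arange(1, int(_ages_series(ages).max()) + 1)
    # indicator genes x strata, so one matmul yields all per-ps sums
    ind = (ps[:, None] == strata[None, :]).astype(np.float64)
    per_ps = X @ ind  # cells x strata
    with np.errstate(invalid="ignore", divide="ignore"):
        ptai = per_ps * strata[None, :] / np.where(denom > 0, denom, np.nan)[:, None]
    return pd.DataFrame(ptai, index=norm.obs_names, columns=pd.Index(strata, name="ps"))


def significance_stars(q: float) -> str:
    if q <= 0.001:
        return "***"
    if q <= 0.01:
        return "**"
    if q <= 0.05:
        return "*"
    return "ns"


def _rank_sum_pair(x: np.ndarray, y: np.ndarray, exact_max: int = 25) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (statistic, p).

    Exact null distribution when both groups are <= ``exact_max`` cells and
    there are no ties; tie-corrected normal approximation otherwise.
    """
    ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    method = "exact" if (max(len(x), len(y)) <= exact_max and not ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    p = float(res.pvalue)
    return float(res.statistic), (p if np.isfinite(p) else 1.0)


def compare_tai(
    tai: pd.Series, labels: pd.Series | np.ndarray, exact_max: int = 25
) -> dict:
    """Kruskal-Wallis omnibus plus BH-adjusted pairwise Wilcoxon tests of
    per-cell TAI across cell types.

    Returns ``{"kruskal_h", "kruskal_p", "pairwise"}`` where ``pairwise``
    is a DataFrame (group1, group2, statistic, p, q, stars).  NaN TAI
    values (cells with no expression on the gene subset) are dropped.
    """
    labels = pd.Series(np.asarray(labels), index=tai.index)
    ok = tai.notna()
    tai, labels = tai[ok], labels[ok]
    groups = {str(g): tai[labels == g].to_numpy() for g in sorted(labels.unique())}
    if len(groups) < 2:
        raise ValueError("need at least two cell types")
    small = [g for g, v in groups.items() if len(v) < 2]
    if small:
        raise ValueError(f"cell types with fewer than 2 cells: {small}")

    h, kp = stats.kruskal(*groups.values())
    rows = []
    for g1, g2 in combinations(groups, 2):
        u, p = _rank_sum_pair(groups[g1], groups[g2], exact_max=exact_max)
        rows.append(dict(group1=g1, group2=g2, statistic=u, p=p))
    pairwise = pd.DataFrame(rows)
    pairwise["q"] = bh_adjust(pairwise["p"].to_numpy())
    pairwise["stars"] = [significance_stars(q) for q in pairwise["q"]]
    return {"kruskal_h": float(h), "kruskal_p": float(kp), "pairwise": pairwise}
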