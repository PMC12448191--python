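"""Upregulated marker (DEG) selection and shared/unique expression partitions.

One-vs-rest Wilcoxon rank-sum per gene with Benjamini-Hochberg correction,
gated on a minimum log2 fold-change of mean normalized expression
(pseudocount 1) and — in "specific" mode — a minimum difference in the
fraction of cells detecting the gene (min.diff.pct).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData
from scipy import stats

from .enrichment import bh_adjust

__all__ = ["DegResult", "select_upregulated_degs", "shared_unique_partition"]


@dataclass
class DegResult:
    """Per-cell-type upregulated gene sets plus the full statistics table.

    ``table`` has one row per (cell_type, gene) that passed every gate,
    with columns p, q, log2fc, diff_pct.  ``params`` records the gates used.
    """

    table: pd.DataFrame
    params: dict = field(default_factory=dict)

    @property
    def sets(self) -> dict[str, set[str]]:
        return {
            str(t): set(g["gene"]) for t, g in self.table.groupby("cell_type", observed=True)
        }

    def genes(self, cell_type: str) -> set[str]:
        return self.sets.get(cell_type, set())

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "DegResult":
        return cls(table=pd.read_csv(path, sep="\t", dtype={"cell_type": str, "gene": str}))


def _dense(X) -> np.ndarray:
    return np.asarray(X.todense()) if sp.issparse(X) else np.asarray(X)


def _rank_sum_pvalues(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Two-sided Wilcoxon rank-sum p per column of (cells x genes) blocks.

    Tie-corrected normal approximation with continuity correction; genes
    where every value is tied (zero rank variance) get p = 1.
    """
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.mannwhitneyu(x, y, axis=0, alternative="two-sided", method="asymptotic")
        p = np.asarray(res.pvalue, dtype=float)
    return np.where(np.isfinite(p), p, 1.0)


def select_upregulated_degs(
    norm: AnnData,
    groupby: str = "cell_type",
    mode: Literal["all", "specific"] = "all",
    logfc_min: float = 0.25,
    min_diff_pct: float = 0.25,
    alpha: float = 0.05,
) -> DegResult:
    """Select upregulated one-vs-rest markers for every cell type.

    A gene is kept for a focal type when its BH-adjusted two-sided Wilcoxon
    rank-sum p is <= ``alpha`` (BH across genes within the focal type), its
    log2 fold-change of mean normalized expression (pseudocount 1) is
    >= ``logfc_min``, and — with ``mode="specific"`` — its detection
    fraction in the focal type exceeds the rest by >= ``min_diff_pct``.
    """
    labels = norm.obs[groupby].astype(str)
    counts = labels.value_counts()
    if len(counts) < 2:
        raise ValueError("need at least two cell types")
    small = counts[counts < 2]
    if len(small):
        raise ValueError(f"cell types with fewer than 2 cells: {small.index.tolist()}")

    X = _dense(norm.X).astype(np.float64)
    genes = norm.var_names.to_numpy()
    rows: list[pd.DataFrame] = []
    for cell_type in sorted(counts.index):
        mask = (labels == cell_type).to_numpy()
        xf, xr = X[mask], X[~mask]
        p = _rank_sum_pvalues(xf, xr)
        q = bh_adjust(p)
        log2fc = np.log2(xf.mean(axis=0) + 1.0) - np.log2(xr.mean(axis=0) + 1.0)
        diff_pct = (xf > 0).mean(axis=0) - (xr > 0).mean(axis=0)
        keep = (q <= alpha) & (log2fc >= logfc_min)
        if mode == "specific":
            keep &= diff_pct >= min_diff_pct
        rows.append(
            pd.DataFrame(
                {
                    "cell_type": cell_type,
                    "gene": genes[keep],
                    "p": p[keep],
                    "q": q[keep],
                    "log2fc": log2fc[keep],
                    "diff_pct": diff_pct[keep],
                }
            )
        )
    table = pd.concat(rows, ignore_index=True)
    params = dict(
        test="wilcoxon_rank_sum", mode=mode, logfc_min=logfc_min,
        min_diff_pct=min_diff_pct, alpha=alpha,
    )
    return DegResult(table=table, params=params)


def shared_unique_partition(
    norm: AnnData,
    gene_ages: pd.Series | Mapping[str, int],
    types: Sequence[str],
    groupby: str = "cell_type",
    detect_frac: float = 0.10,
) -> pd.DataFrame:
    """Venn-region sizes of expressed genes among cell types, per phylostratum.

    A gene counts as expressed in a type when it is detected (count > 0) in
    at least ``detect_frac`` of that type's cells.  Returns a DataFrame
    indexed by ps with one column per nonempty type combination (names
    joined by ``&``); region sizes over one ps sum to the number of
    age-mapped genes expressed in at least one of the chosen types.
    """
    labels = norm.obs[groupby].astype(str)
    unknown = sorted(set(types) - set(labels))
    if unknown:
        raise ValueError(f"unknown cell type labels: {unknown}")
    ages = pd.Series(gene_ages) if not isinstance(gene_ages, pd.Series) else gene_ages
    aged = norm.var_names.intersection(ages.index)
    X = _dense(norm[:, aged].X)

    expressed = {}
    for t in types:
        mask = (labels == t).to_numpy()
        expressed[t] = (X[mask] > 0).mean(axis=0) >= detect_frac

    gene_ps = ages.loc[aged].astype(int).to_numpy()
    ps_values = np.unique(gene_ps)
    combos = []
    for r in range(1, len(types) + 1):
        from itertools import combinations

        combos.extend(combinations(types, r))
    out = pd.DataFrame(0, index=pd.Index(ps_values, name="ps"),
                       columns=["&".join(c) for c in combos], dtype=int)
    membership = np.stack([expressed[t] for t in types])  # types x genes
    any_expr = membership.any(axis=0)
    for combo in combos:
        in_combo = np.array([t in combo for t in types])
        region = membership[in_combo].all(axis=0) & ~membership[~in_combo].any(axis=0) \
            if (~in_combo).any() else membership.all(axis=0)
        region &= any_expr
        for ps in ps_values:
            out.loc[ps, "&".join(combo)] = int(np.sum(region & (gene_ps == ps)))
    return out
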