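"""Phylostratum enrichment of DEG sets: two-sided hypergeometric tests,
log-odds effect sizes, and Benjamini-Hochberg FDR control.

Each cell type's upregulated DEGs (the test set) are compared against a
background DEG set (union over the user-chosen background cell types): for
every phylostratum the number of test-set genes of that age is tested
against the hypergeometric expectation from the background, two-sided by
the minimum-likelihood rule.  Effect sizes are log2 odds ratios with a
Haldane-Anscombe 0.5 pseudocount so depletion down to k = 0 stays finite;
log-odds of zero means the observed DEG frequency in a phylostratum equals
the background expectation.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["fisher_two_sided", "bh_adjust", "log_odds", "ps_enrichment"]

# Relative slack when comparing outcome likelihoods: outcomes with
# pmf <= pmf(k) * (1 + _REL_SLACK) are counted in the two-sided tail.
_REL_SLACK = 1e-7


def _check_margins(k: int, n: int, K: int, N: int) -> None:
    if not (0 <= n <= N and 0 <= K <= N):
        raise ValueError(f"inconsistent margins: n={n}, K={K}, N={N}")
    lo, hi = max(0, n - (N - K)), min(n, K)
    if not (lo <= k <= hi):
        raise ValueError(f"k={k} outside the hypergeometric support [{lo}, {hi}]")


def _two_sided_pvalues(n: int, K: int, N: int) -> tuple[np.ndarray, np.ndarray]:
    """Minimum-likelihood two-sided p for every k in the support.

    Returns (support, pvalues).  p(k) is the total probability of all
    outcomes no more likely than k, the convention of standard exact-test
    implementations.
    """
    lo, hi = max(0, n - (N - K)), min(n, K)
    support = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(support, N, K, n)
    order = np.argsort(pmf, kind="stable")
    cum = np.cumsum(pmf[order])
    # rank of the largest pmf value still counted as "no more likely than k"
    sorted_pmf = pmf[order]
    idx = np.searchsorted(sorted_pmf, pmf * (1.0 + _REL_SLACK), side="right") - 1
    p = cum[idx]
    p = np.minimum(np.maximum(p, np.finfo(float).tiny), 1.0)
    return support, p


def fisher_two_sided(k: int, n: int, K: int, N: int) -> float:
    """Two-sided hypergeometric p for observing ``k`` test-set members of a
    category, in ``n`` draws from a population of ``N`` containing ``K``
    members of the category.

    Two-siding follows the minimum-likelihood rule: the p-value sums the
    probabilities of all outcomes whose probability does not exceed that of
    the observed ``k`` (with a small relative slack for floating-point
    ties).  Always in (0, 1].
    """
    k, n, K, N = int(k), int(n), int(K), int(N)
    _check_margins(k, n, K, N)
    support, p = _two_sided_pvalues(n, K, N)
    return float(p[k - support[0]])


def bh_adjust(pvalues: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, q >= p)."""
    p = np.asarray(list(pvalues) if not isinstance(pvalues, np.ndarray) else pvalues, float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def log_odds(k: int, n: int, K: int, N: int, pseudocount: float = 0.5) -> float:
    """log2 odds ratio of category membership, test set vs rest of background.

    Haldane-Anscombe corrected: ``pseudocount`` is added to all four cells
    of the (in-category vs not) x (test vs rest) table, keeping the value
    finite at k = 0 and k = n.  Positive values mean over-representation.
    """
    a = k + pseudocount                      # test, in category
    b = (n - k) + pseudocount                # test, out
    c = (K - k) + pseudocount                # rest of background, in
    d = ((N - n) - (K - k)) + pseudocount    # rest of background, out
    return float(np.log2((a / b) / (c / d)))


def ps_enrichment(
    deg_sets: Mapping[str, set] | "DegResult",
    background_types: Sequence[str],
    ages: pd.Series | Mapping[str, int] | "GeneAgeMap",
    test_types: Sequence[str] | None = None,
    n_ps: int | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Phylostratum enrichment of each cell type's DEGs against a background.

    The background is the union of DEG sets over ``background_types``; a
    test set not fully contained in it is unioned in (its own genes belong
    to the sampled universe).  Genes without an age assignment are dropped
    (per-type counts reported in ``attrs["n_unmapped"]``).  BH correction is
    applied across every (cell type, ps) cell of the table.

    Returns a DataFrame with columns cell_type, ps, k, n, K, N, log_odds,
    p, q, significant.
    """
    if hasattr(deg_sets, "sets"):
        deg_sets = deg_sets.sets
    if hasattr(ages, "ages"):
        ages = ages.ages
    ages = pd.Series(ages) if not isinstance(ages, pd.Series) else ages
    ages = ages.astype(int)

    missing = sorted(set(background_types) - set(deg_sets))
    if missing:
        raise ValueError(f"background types without DEG sets: {missing}")
    background = set().union(*(deg_sets[t] for t in background_types))
    if not background:
        raise ValueError("background DEG set is empty")
    if test_types is None:
        test_types = sorted(deg_sets)

    if n_ps is None:
        n_ps = int(ages.max())
    strata = np.arange(1, n_ps + 1)

    rows = []
    n_unmapped: dict[str, int] = {}
    for cell_type in test_types:
        test = set(deg_sets[cell_type])
        if not test:
            raise ValueError(f"empty test set for cell type {cell_type!r}")
        universe = background | test
        mapped = ages.index.intersection(universe)
        n_unmapped[cell_type] = len(universe) - len(mapped)
        uni_ages = ages.loc[mapped]
        test_ages = uni_ages.loc[uni_ages.index.isin(test)]
        N = len(uni_ages)
        n = len(test_ages)
        K_per_ps = uni_ages.value_counts().reindex(strata, fill_value=0)
        k_per_ps = test_ages.value_counts().reindex(strata, fill_value=0)
        for ps in strata:
            K, k = int(K_per_ps[ps]), int(k_per_ps[ps])
            rows.append(
                dict(
                    cell_type=cell_type, ps=int(ps), k=k, n=n, K=K, N=N,
                    log_odds=log_odds(k, n, K, N),
                    p=fisher_two_sided(k, n, K, N),
                )
            )
    table = pd.DataFrame(rows)
    table["q"] = bh_adjust(table["p"].to_numpy())
    table["significant"] = table["q"] <= alpha
    table.attrs["n_unmapped"] = n_unmapped
    table.attrs["background_types"] = list(background_types)
    return table
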