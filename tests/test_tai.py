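"""Transcriptome age index, partial decomposition, and group comparisons."""

import numpy as np
import pandas as pd
import pytest
from anndata import AnnData

from sctai import compare_tai, compute_partial_tai, compute_tai, downsample_cells
from sctai.tai import significance_stars

from conftest import random_norm_adata


def brute_force_tai(X, ps):
    """Naive per-cell loop: weighted mean of ps with expression weights."""
    out = []
    for c in range(X.shape[0]):
        num = den = 0.0
        for i in range(X.shape[1]):
            num += ps[i] * X[c, i]
            den += X[c, i]
        out.append(num / den if den > 0 else np.nan)
    return np.array(out)


def brute_force_ptai(X, ps, strata):
    out = np.zeros((X.shape[0], len(strata)))
    for c in range(X.shape[0]):
        den = X[c].sum()
        for j, s in enumerate(strata):
            out[c, j] = s * X[c, ps == s].sum() / den
    return out


class TestComputeTai:
    def test_worked_micro_example(self, micro_adata, micro_ages):
        # ps {1,2}, e {3,1}: TAI = (1*3 + 2*1) / 4 = 1.25
        tai = compute_tai(micro_adata, micro_ages)
        assert tai.iloc[0] == pytest.approx(1.25, abs=1e-12)

    def test_uniform_age_gives_that_age(self):
        a = AnnData(X=np.array([[5.0, 1.0], [2.0, 9.0]]))
        ages = pd.Series(1, index=a.var_names)
        assert np.allclose(compute_tai(a, ages), 1.0)

    def test_scale_invariance_per_cell(self):
        rng = np.random.default_rng(2)
        a, ages = random_norm_adata(rng)
        t1 = compute_tai(a, ages)
        a2 = a.copy()
        a2.X[3] *= 10.0
        t2 = compute_tai(a2, ages)
        assert np.allclose(t1, t2, rtol=1e-12, equal_nan=True)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(5)
        a, ages = random_norm_adata(rng, n_genes=50, n_cells=20)
        got = compute_tai(a, ages).to_numpy()
        want = brute_force_tai(np.asarray(a.X), ages.to_numpy())
        assert np.allclose(got, want, rtol=1e-12, equal_nan=True)

    def test_unmapped_and_zero_genes_do_not_contribute(self):
        a = AnnData(X=np.array([[3.0, 1.0, 50.0, 0.0]]))
        ages = pd.Series({"0": 1, "1": 2, "3": 7})  # gene "2" has no age
        assert compute_tai(a, ages).iloc[0] == pytest.approx(1.25)

    def test_all_zero_restricted_cell_is_nan(self):
        a = AnnData(X=np.array([[0.0, 5.0], [1.0, 1.0]]))
        ages = pd.Series({"0": 3, "1": 4})
        tai = compute_tai(a, ages, gene_subset={"0"})
        assert np.isnan(tai.iloc[0]) and tai.iloc[1] == 3.0

    def test_no_age_mapped_genes_is_error(self):
        a = AnnData(X=np.ones((2, 2)))
        with pytest.raises(ValueError, match="age-mapped"):
            compute_tai(a, pd.Series({"zz": 1}))


class TestPartialTai:
    def test_single_stratum_equals_tai(self):
        a = AnnData(X=np.array([[2.0, 3.0]]))
        ages = pd.Series({"0": 4, "1": 4})
        ptai = compute_partial_tai(a, ages)
        assert ptai.loc[:, 4].iloc[0] == pytest.approx(4.0)
        assert ptai.drop(columns=4).to_numpy().sum() == 0.0

    def test_worked_micro_example(self, micro_adata, micro_ages):
        ptai = compute_partial_tai(micro_adata, micro_ages)
        assert ptai.iloc[0].tolist() == pytest.approx([0.75, 0.5])

    def test_matches_brute_force(self):
        rng = np.random.default_rng(9)
        a, ages = random_norm_adata(rng, n_genes=50, n_cells=20)
        strata = np.arange(1, ages.max() + 1)
        got = compute_partial_tai(a, ages).to_numpy()
        want = brute_force_ptai(np.asarray(a.X), ages.to_numpy(), strata)
        assert np.allclose(got, want, rtol=1e-12, equal_nan=True)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_decomposition_identity_and_bounds(self, seed):
        rng = np.random.default_rng(seed)
        a, ages = random_norm_adata(rng, n_genes=80, n_cells=40)
        tai = compute_tai(a, ages).to_numpy()
        ptai = compute_partial_tai(a, ages)
        ok = ~np.isnan(tai)
        assert np.allclose(ptai.to_numpy()[ok].sum(axis=1), tai[ok], rtol=1e-9)
        assert (ptai.to_numpy()[ok] >= 0).all()
        assert (tai[ok] >= 1).all() and (tai[ok] <= ages.max()).all()

    def test_adding_unexpressed_gene_changes_nothing(self):
        rng = np.random.default_rng(12)
        a, ages = random_norm_adata(rng, n_genes=30, n_cells=10)
        X2 = np.hstack([np.asarray(a.X), np.zeros((10, 1))])
        a2 = AnnData(
            X=X2,
            obs=a.obs.copy(),
            var=pd.DataFrame(index=list(a.var_names) + ["silent"]),
        )
        ages2 = pd.concat([ages, pd.Series({"silent": 2})])
        assert np.allclose(
            compute_tai(a, ages), compute_tai(a2, ages2), rtol=1e-12, equal_nan=True
        )
        pd.testing.assert_frame_equal(
            compute_partial_tai(a, ages), compute_partial_tai(a2, ages2),
            check_names=False,
        )


class TestCompareTai:
    def test_identical_groups_nonsignificant(self):
        vals = np.tile(np.arange(20.0), 2)
        tai = pd.Series(vals, index=[f"c{i}" for i in range(40)])
        labels = ["A"] * 20 + ["B"] * 20
        res = compare_tai(tai, labels)
        assert res["pairwise"]["p"].iloc[0] > 0.9
        assert res["pairwise"]["stars"].iloc[0] == "ns"

    def test_planted_shift_detected(self, norm_default):
        norm, truth = norm_default
        tai = compute_tai(norm, truth.gene_ages)
        res = compare_tai(tai, norm.obs["cell_type"])
        pair = res["pairwise"].set_index(["group1", "group2"])
        key = ("HC", "IC") if ("HC", "IC") in pair.index else ("IC", "HC")
        assert res["kruskal_p"] < 1e-6
        assert pair.loc[key, "q"] < 0.05
        med = tai.groupby(norm.obs["cell_type"]).median()
        assert med["IC"] < med["OB"] and med["IC"] < med["HC"]

    def test_small_group_error(self):
        tai = pd.Series([1.0, 2.0, 3.0], index=list("abc"))
        with pytest.raises(ValueError):
            compare_tai(tai, ["A", "A", "B"])

    def test_stars_thresholds(self):
        assert significance_stars(0.0005) == "***"
        assert significance_stars(0.005) == "**"
        assert significance_stars(0.05) == "*"
        assert significance_stars(0.2) == "ns"

    def test_downsampling_robustness(self, norm_default):
        # per-type median TAI from n=50 subsamples tracks the full-data
        # median within sampling noise (20 seeds)
        norm, truth = norm_default
        tai = compute_tai(norm, truth.gene_ages)
        labels = norm.obs["cell_type"]
        full = tai.groupby(labels).median()
        sub_medians = []
        for seed in range(20):
            idx = downsample_cells(labels, 50, seed=seed)
            sub_medians.append(tai.iloc[idx].groupby(labels.iloc[idx]).median())
        sub = pd.DataFrame(sub_medians)
        assert (np.abs(sub.mean() - full) < 0.05).all()
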