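import numpy as np
import pandas as pd
import pytest
from anndata import AnnData

from sctai import (
    build_phylostratum_index,
    default_design,
    filter_cells,
    filter_genes,
    generate_dataset,
    normalize_total,
)


@pytest.fixture(scope="session")
def toy_index():
    """22-node index with two taxa per node plus the focal taxon on node 22."""
    from sctai import synthetic_phylostratigraphy

    return synthetic_phylostratigraphy(n_ps=22, n_taxa_per_ps=2)


@pytest.fixture(scope="session")
def micro_adata():
    """One cell, two genes with ages {1, 2} and normalized expression {3, 1}."""
    return AnnData(
        X=np.array([[3.0, 1.0]]),
        obs=pd.DataFrame(index=["c1"]),
        var=pd.DataFrame(index=["gA", "gB"]),
    )


@pytest.fixture(scope="session")
def micro_ages():
    return pd.Series({"gA": 1, "gB": 2})


@pytest.fixture(scope="session")
def sim_default():
    """Reference synthetic dataset (ancestral vs young skeletal programs)."""
    adata, truth = generate_dataset(default_design(seed=11))
    return adata, truth


@pytest.fixture(scope="session")
def norm_default(sim_default):
    """QC-filtered, CPM(1e6)-normalized version of the reference dataset."""
    adata, truth = sim_default
    a = filter_genes(filter_cells(adata))
    return normalize_total(a), truth


def random_norm_adata(rng, n_genes=50, n_cells=20, n_ps=20):
    """Small dense normalized-expression AnnData with random gene ages."""
    X = rng.gamma(2.0, 50.0, size=(n_cells, n_genes)) * rng.integers(
        0, 2, size=(n_cells, n_genes)
    )
    genes = [f"g{i:03d}" for i in range(n_genes)]
    cells = [f"c{i:03d}" for i in range(n_cells)]
    adata = AnnData(
        X=X, obs=pd.DataFrame(index=cells), var=pd.DataFrame(index=genes)
    )
    ages = pd.Series(rng.integers(1, n_ps + 1, size=n_genes), index=genes)
    return adata, ages
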