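"""Synthetic phylostratum-annotated single-cell datasets with planted,
age-biased expression programs.

The generator emulates the statistical structure the downstream analysis
assumes: a sparse negative-binomial count matrix over ~20 phylostrata,
several labeled cell types, mitochondrial genes, log-normal library-size
variation, and cell-type-specific marker programs that over-express genes
from designated phylostrata (an "old-transcriptome" chondrocyte-like type
vs "young-transcriptome" hypertrophic/osteoblast-like types).  The planted
truth (gene ages, markers, enriched strata) is returned alongside the data
so every pipeline stage can be checked against it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData

from .phylostrata import Phylostratigraphy, build_phylostratum_index

__all__ = [
    "CellTypeSpec",
    "SimDesign",
    "SimTruth",
    "default_design",
    "null_design",
    "generate_dataset",
    "generate_hit_table",
    "synthetic_phylostratigraphy",
]


@dataclass(frozen=True)
class CellTypeSpec:
    """One simulated cell type: its planted program maps phylostrata to the
    fold by which that type's marker genes from the stratum are boosted."""

    name: str
    n_cells: int
    program: Mapping[int, float] = field(default_factory=dict)
    n_marker_genes: int = 0

    def __post_init__(self):
        if self.n_cells < 2:
            raise ValueError(f"{self.name}: n_cells must be >= 2")
        if any(f <= 0 for f in self.program.values()):
            raise ValueError(f"{self.name}: program folds must be > 0")


@dataclass(frozen=True)
class SimDesign:
    """Design of a synthetic dataset.

    Counts are negative binomial (Gamma-Poisson) with mean
    ``base_mean * library_factor * program_fold`` and dispersion
    ``dispersion`` (variance mu + mu^2 / dispersion); library factors are
    log-normal with sigma ``libsize_sigma``.  A small fraction of cells is
    emitted damaged (high mitochondrial content) or shallow (tiny library)
    so the QC filters have work to do.  ``frac_unaged`` of genes carries no
    age (no self-match in the homology table), exercising the discard path.
    """

    n_ps: int = 22
    genes_per_ps: int | Sequence[int] = 250
    cell_types: tuple[CellTypeSpec, ...] = ()
    base_mean: float = 0.3
    dispersion: float = 2.0
    libsize_sigma: float = 0.35
    n_mito_genes: int = 10
    mito_mean: float = 9.0
    frac_high_mito: float = 0.02
    high_mito_fold: float = 8.0
    frac_shallow: float = 0.02
    shallow_factor: float = 0.02
    frac_unaged: float = 0.01
    seed: int = 0

    def genes_vector(self) -> np.ndarray:
        g = self.genes_per_ps
        v = np.full(self.n_ps, g, dtype=int) if np.isscalar(g) else np.asarray(g, dtype=int)
        if len(v) != self.n_ps or (v < 1).any():
            raise ValueError("genes_per_ps must give >= 1 gene for every ps")
        return v

    def validate(self) -> None:
        v = self.genes_vector()
        if not self.cell_types:
            raise ValueError("design has no cell types")
        names = [t.name for t in self.cell_types]
        if len(set(names)) != len(names):
            raise ValueError("duplicate cell type names")
        for t in self.cell_types:
            for ps in t.program:
                if not (1 <= ps <= self.n_ps):
                    raise ValueError(f"{t.name}: program ps {ps} outside 1..{self.n_ps}")


@dataclass
class SimTruth:
    """Planted ground truth of a generated dataset."""

    gene_ages: pd.Series  # aged genes only, gene_id -> ps
    unaged_genes: list[str]
    marker_genes: dict[str, list[str]]
    planted_ps: dict[str, list[int]]
    expected_tai_order: list[str]  # old -> young by planted program age
    design: SimDesign


def default_design(seed: int = 0) -> SimDesign:
    """The reference design: an ancestral chondrocyte-like type (old-gene
    program, ps 1-4) against two young-program skeletal types with markers
    from the vertebrate (ps 11) and gnathostome (ps 12) strata, fold 8,
    100 cells per type."""
    return SimDesign(
        cell_types=(
            CellTypeSpec("IC", 100, {1: 8.0, 2: 8.0, 3: 8.0, 4: 8.0}, 200),
            CellTypeSpec("OB", 100, {11: 8.0}, 100),
            CellTypeSpec("HC", 100, {11: 8.0, 12: 8.0}, 240),
        ),
        seed=seed,
    )


def null_design(
    seed: int = 0, n_types: int = 3, n_cells: int = 25, genes_per_ps: int = 20
) -> SimDesign:
    """A no-signal design (no programs): all types exchangeable."""
    return SimDesign(
        n_ps=22,
        genes_per_ps=genes_per_ps,
        cell_types=tuple(
            CellTypeSpec(f"T{i + 1}", n_cells, {}, 0) for i in range(n_types)
        ),
        mito_mean=1.0,  # keep mito content ~5% of the smaller transcriptome
        frac_high_mito=0.0,
        frac_shallow=0.0,
        seed=seed,
    )


def _program_age(spec: CellTypeSpec, n_ps: int) -> float:
    if not spec.program:
        return (1 + n_ps) / 2.0
    w = np.array(list(spec.program.values()), float)
    p = np.array(list(spec.program.keys()), float)
    return float((w * p).sum() / w.sum())


def generate_dataset(design: SimDesign) -> tuple[AnnData, SimTruth]:
    """Draw a synthetic labeled count matrix plus its planted truth.

    Returns an :class:`AnnData` (cells x genes, raw integer counts in a
    sparse ``X``, ``obs["cell_type"]`` labels) and the :class:`SimTruth`.
    Output is bit-identical for a fixed design (including its seed).
    """
    design.validate()
    rng = np.random.default_rng(design.seed)
    genes_v = design.genes_vector()

    gene_ids: list[str] = []
    gene_ps: list[int] = []
    for ps, g in zip(range(1, design.n_ps + 1), genes_v):
        for i in range(g):
            gene_ids.append(f"g_ps{ps:02d}_{i:04d}")
            gene_ps.append(ps)
    mito_ids = [f"mt-g{i:02d}" for i in range(design.n_mito_genes)]
    gene_ids += mito_ids
    gene_ps += [1] * design.n_mito_genes  # mitochondrial genes are ancient
    gene_ids = np.array(gene_ids)
    gene_ps_arr = np.array(gene_ps)
    n_genes = len(gene_ids)
    is_mito = np.zeros(n_genes, bool)
    is_mito[-design.n_mito_genes:] = design.n_mito_genes > 0

    # per-(type, ps) disjoint marker pools, claimed in declaration order
    claimed = np.zeros(n_genes, bool)
    marker_genes: dict[str, list[str]] = {}
    fold_matrix = np.ones((len(design.cell_types), n_genes))
    for ti, spec in enumerate(design.cell_types):
        markers: list[str] = []
        if spec.program and spec.n_marker_genes > 0:
            strata = sorted(spec.program)
            share = np.full(len(strata), spec.n_marker_genes // len(strata))
            share[: spec.n_marker_genes % len(strata)] += 1
            for ps, k in zip(strata, share):
                pool = np.flatnonzero((gene_ps_arr == ps) & ~claimed & ~is_mito)
                if len(pool) < k:
                    raise ValueError(
                        f"{spec.name}: needs {k} markers in ps {ps}, pool has {len(pool)}"
                    )
                pick = rng.choice(pool, size=k, replace=False)
                claimed[pick] = True
                fold_matrix[ti, pick] = spec.program[ps]
                markers.extend(gene_ids[pick])
        marker_genes[spec.name] = sorted(markers)

    cells_type_idx = np.concatenate(
        [np.full(spec.n_cells, ti) for ti, spec in enumerate(design.cell_types)]
    )
    n_cells = len(cells_type_idx)
    labels = np.array([design.cell_types[ti].name for ti in cells_type_idx])
    cell_ids = np.array([f"cell_{i:05d}" for i in range(n_cells)])

    lib = np.exp(rng.normal(0.0, design.libsize_sigma, size=n_cells))
    shallow = rng.random(n_cells) < design.frac_shallow
    lib[shallow] *= design.shallow_factor
    mito_mult = np.ones(n_cells)
    high_mito = rng.random(n_cells) < design.frac_high_mito
    mito_mult[high_mito] *= design.high_mito_fold

    mean = design.base_mean * fold_matrix[cells_type_idx, :]
    mean[:, is_mito] = design.mito_mean * mito_mult[:, None]
    mean *= lib[:, None]

    lam = rng.gamma(shape=design.dispersion, scale=mean / design.dispersion)
    counts = rng.poisson(lam).astype(np.int32)

    adata = AnnData(
        X=sp.csr_matrix(counts),
        obs=pd.DataFrame({"cell_type": labels}, index=cell_ids),
        var=pd.DataFrame({"true_ps": gene_ps_arr, "is_mito": is_mito}, index=gene_ids),
    )
    adata.uns["sim_seed"] = int(design.seed)

    unaged_idx = rng.choice(
        np.flatnonzero(~is_mito),
        size=int(round(design.frac_unaged * (n_genes - design.n_mito_genes))),
        replace=False,
    )
    unaged = set(gene_ids[unaged_idx])
    aged_mask = ~np.isin(gene_ids, list(unaged))
    ages = pd.Series(gene_ps_arr[aged_mask], index=gene_ids[aged_mask]).sort_index()

    order = sorted(design.cell_types, key=lambda s: _program_age(s, design.n_ps))
    truth = SimTruth(
        gene_ages=ages,
        unaged_genes=sorted(unaged),
        marker_genes=marker_genes,
        planted_ps={s.name: sorted(s.program) for s in design.cell_types},
        expected_tai_order=[s.name for s in order],
        design=design,
    )
    return adata, truth


def synthetic_phylostratigraphy(
    n_ps: int = 22, n_taxa_per_ps: int = 2, focal_taxon: str = "taxon_focal"
) -> Phylostratigraphy:
    """A toy phylostratum index with ``n_taxa_per_ps`` subject taxa on every
    node and the focal taxon on the terminal one."""
    nodes = pd.DataFrame(
        {"ps": range(1, n_ps + 1), "node_name": [f"node{p:02d}" for p in range(1, n_ps + 1)]}
    )
    taxa = [
        (f"taxon_ps{p:02d}_{i}", p)
        for p in range(1, n_ps + 1)
        for i in range(n_taxa_per_ps)
    ]
    taxa.append((focal_taxon, n_ps))
    return build_phylostratum_index(
        nodes, pd.DataFrame(taxa, columns=["taxon_id", "ps"])
    )


def generate_hit_table(
    truth: SimTruth,
    index: Phylostratigraphy,
    seed: int = 0,
    focal_taxon: str = "taxon_focal",
    n_extra_hits: int = 3,
    decoy_prob: float = 0.3,
) -> pd.DataFrame:
    """Emit a homology-hit table whose oldest-internode assignment recovers
    ``truth.gene_ages`` exactly.

    Every aged gene gets a self-hit, at least one hit to a taxon at exactly
    its planted ps, extra hits only to taxa at the same or younger strata,
    and (with probability ``decoy_prob``) a decoy hit to an older taxon
    with an e-value above the standard 1e-3 threshold, which the filter
    must ignore.  Genes planted as unaged get hits but no self-match, so
    assignment drops them.
    """
    rng = np.random.default_rng(seed)
    P = index.n_strata
    taxa_by_ps = {p: [t for t in index.taxa_at(p) if t != focal_taxon] for p in range(1, P + 1)}
    for ps in set(truth.gene_ages.unique()):
        if not taxa_by_ps[int(ps)]:
            raise ValueError(f"index has no non-focal taxa at planted ps {ps}")

    rows: list[tuple[str, str, float]] = []

    def _evalue() -> float:
        return 10.0 ** (-rng.uniform(5.0, 50.0))

    for gene, age in truth.gene_ages.items():
        age = int(age)
        rows.append((gene, focal_taxon, 1e-180))
        rows.append((gene, rng.choice(taxa_by_ps[age]), _evalue()))
        for _ in range(int(rng.integers(0, n_extra_hits + 1))):
            ps = int(rng.integers(age, P + 1))
            pool = taxa_by_ps[ps] or [focal_taxon]
            rows.append((gene, rng.choice(pool), _evalue()))
        if age > 1 and rng.random() < decoy_prob:
            older = int(rng.integers(1, age))
            if taxa_by_ps[older]:
                rows.append((gene, rng.choice(taxa_by_ps[older]), 10.0 ** rng.uniform(-2.5, 0)))

    for gene in truth.unaged_genes:
        for _ in range(int(rng.integers(1, 4))):
            ps = int(rng.integers(1, P + 1))
            if taxa_by_ps[ps]:
                rows.append((gene, rng.choice(taxa_by_ps[ps]), _evalue()))

    hits = pd.DataFrame(rows, columns=["query", "subject_taxon", "evalue"])
    return hits.sample(frac=1.0, random_state=int(rng.integers(0, 2**31))).reset_index(drop=True)
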