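# sctai — single-cell phylotranscriptomics

`sctai` dates cell-type transcriptomes on an evolutionary timescale. It is
aimed at researchers studying cell-type evolution who have (a) a
phylostratigraphic map — each gene assigned to the oldest phylogenetic node
(phylostratum, ps) at which sequence homology is still detectable — and
(b) a labeled single-cell RNA-seq count matrix. The package covers the full
analysis chain:

* **Gene ages** — build a phylostratum index (ordered nodes 1..P plus a
  taxon→node map) and assign each gene its age from a tabular homology-hit
  file by the oldest-internode rule, discarding queries without a
  self-match (e-value threshold 1e-3 by default).
* **QC and normalization** — retain cells with 200–5,000 detected genes and
  ≤20% mitochondrial reads, genes detected in ≥10 cells; per-cell
  total-count normalization to 10⁶.
* **Transcriptome age index** — per cell c,
  `TAI_c = Σᵢ psᵢ·e_ic / Σᵢ e_ic`, the expression-weighted mean
  phylostratum (low = evolutionarily old transcriptome); its partial
  decomposition `pTAI_jc = ps_j·Σ_{i∈ps j} e_ic / Σᵢ e_ic` with
  `Σ_j pTAI_jc = TAI_c`; Kruskal–Wallis and pairwise Wilcoxon (BH)
  comparisons across cell types, with optional restriction to specifically
  expressed genes and per-type downsampling (n = 50/100).
* **Profiles** — mean expression per (ps, cell type) and its min–max
  relative transform `RE = (f̄ − f̄_min)/(f̄_max − f̄_min)`; shared/unique
  expressed-gene partitions across cell types per ps.
* **Enrichment** — each cell type's upregulated markers (one-vs-rest
  Wilcoxon, min.diff.pct gate) tested per phylostratum against a background
  DEG set: minimum-likelihood two-sided hypergeometric p, Haldane-corrected
  log2 odds ratios, BH across the table.
* **Synthetic data** — a negative-binomial simulator that plants
  age-biased programs (old-transcriptome vs young-transcriptome cell
  types) with known truth, so the whole chain is testable without any
  download.

See `docs/methods.md` for conventions, defaults, and limitations.

## Worked example

Simulate the reference design — an ancestral chondrocyte-like type (IC,
markers from ps 1–4), an osteoblast-like type (OB, ps 11) and a
hypertrophic-chondrocyte-like type (HC, ps 11–12), 100 cells each, fold 8 —
then run the chain end to end:

```python
from sctai import (
    default_design, generate_dataset, generate_hit_table,
    synthetic_phylostratigraphy, assign_gene_ages, filter_cells,
    filter_genes, normalize_total, compute_tai, compare_tai,
    select_upregulated_degs, ps_enrichment,
)

adata, truth = generate_dataset(default_design(seed=0))
index = synthetic_phylostratigraphy(n_ps=22)
hits = generate_hit_table(truth, index, seed=0)
ages = assign_gene_ages(hits, index, evalue_threshold=1e-3,
                        focal_taxon="taxon_focal")
print(f"genes age-mapped: {len(ages)}  discarded: {ages.n_discarded}")

norm = normalize_total(filter_genes(filter_cells(adata)))
tai = compute_tai(norm, ages)
print(tai.groupby(norm.obs["cell_type"]).median().round(2).to_string())
print(compare_tai(tai, norm.obs["cell_type"])["pairwise"].to_string(index=False))

degs = select_upregulated_degs(norm, mode="all")
enr = ps_enrichment(degs, ["IC", "OB", "HC"], ages)
print(enr[enr.significant].sort_values("log_odds", ascending=False)
      .head(4)[["cell_type", "ps", "k", "n", "log_odds", "q"]]
      .round(3).to_string(index=False))
```

Output:

```
genes age-mapped: 5455  discarded: 55
cell_type
HC    11.08
IC     9.33
OB    10.94
group1 group2  statistic            p            q stars
    HC     IC     9024.0 1.127171e-32 3.381513e-32   ***
    HC     OB     6646.0 1.807705e-08 1.807705e-08   ***
    IC     OB        0.0 2.380229e-32 3.570344e-32   ***
cell_type  ps   k   n  log_odds   q
       HC  12 120 251     9.203 0.0
       IC   2  50 205     7.899 0.0
       IC   4  50 205     6.310 0.0
       IC   3  50 205     5.569 0.0
```

Reading it: 55 of 5,510 simulated genes lack a self-match and are dropped
from the age map. The ancestral type (IC) has the lowest median TAI (9.33 —
oldest transcriptome) and the hypertrophic type the highest (11.08), every
pairwise difference significant after BH. Enrichment recovers the planted
structure: the HC marker set is massively over-represented in ps 12
(120 of its 251 DEGs; log-odds 9.2), and IC markers concentrate in the old
strata 2–4.

## Command line

Every stage is also a subcommand of the `sctai` console script —
`assign-ages`, `qc`, `degs`, `venn`, `tai`, `ptai`, `tai-compare`,
`ps-profile`, `enrich`, `simulate`, and `run`, which executes the whole
chain from a YAML config and writes every intermediate table plus a
manifest of parameters, seeds, and stage-by-stage counts:

```sh
sctai simulate --seed 0 -o data/
sctai run --config run.yaml
```

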