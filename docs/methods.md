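# Methods

`sctai` implements a single-cell phylotranscriptomic analysis chain: assign
every protein-coding gene an evolutionary age (phylostratum), weight those
ages by single-cell expression to date each cell's transcriptome, and test
which phylostrata contributed disproportionately to each cell type's marker
program. This note documents the models, the conventions chosen where the
procedure admits more than one reading, and the limits of what the
simulation-based tests demonstrate.

## Gene ages: genomic phylostratigraphy

A phylostratum (ps) is a node on the focal species' lineage, numbered from
the root (ps 1, cellular organisms) to the terminal branch (ps P, the focal
species; P = 22 for mouse-style indices). The input is a tabular projection
of a protein sequence-similarity search: one row per (query gene, subject
taxon, e-value). Running the search itself is out of scope.

Assignment follows the oldest-internode rule: keep hits with
e-value <= threshold (default 1e-3, inclusive so boundary rows behave
deterministically), discard any query without a retained self-match, and
give every other query the smallest ps among its retained hits' taxa. Ties
cannot occur (minimum over integers), so the result is independent of row
order.

Self-match granularity is a genuine ambiguity: tabular hit files do not
always carry subject gene ids, so by default a retained hit to the focal
*taxon* counts as self-coverage. When subject gene ids are present,
`self_rule="gene"` requires `subject_gene == query` instead. Unknown subject
taxa are hard errors rather than silently skipped — they almost always mean
the hit table and the index disagree about taxon naming.

## Single-cell QC and normalization

Filters run in this order: cell filters first, then the gene-prevalence
filter (detected-gene counts per cell therefore refer to the unfiltered gene
panel). Conventions, chosen as the strict reading of the usual phrasing and
pinned by tests:

| parameter       | default | retained when            |
|-----------------|---------|--------------------------|
| `min_genes`     | 200     | detected genes >= 200    |
| `max_genes`     | 5000    | detected genes <= 5000   |
| `max_mito`      | 0.20    | mito fraction <= 0.20    |
| `min_cells`     | 10      | gene detected in >= 10 cells |

Mitochondrial genes are recognized by a configurable id prefix (default
`mt-`, case-insensitive); a precomputed `mito_fraction` column in the
annotation takes precedence. Normalization is per-cell total-count scaling
to `scale_factor` (default 1e6, i.e. counts per million); per-cell TAI is
scale-invariant, so the factor matters only for expression profiles.

## Transcriptome age index

For cell c with normalized expression e_ic over the n age-mapped genes,

    TAI_c = Σ_i ps_i e_ic / Σ_i e_ic ,

an expression-weighted mean age: low TAI = evolutionarily old transcriptome.
The partial TAI of stratum j, pTAI_jc = ps_j Σ_{i∈j} e_ic / Σ_i e_ic, is
j's additive share, and Σ_j pTAI_jc = TAI_c exactly (asserted to 1e-9
relative in tests). Genes expressed but lacking an age are excluded from
numerator and denominator both; a cell whose (possibly subset-restricted)
expression is all zero gets NaN, never 0, because 0 would read as "older
than the root".

Cell types are compared by a Kruskal–Wallis omnibus plus pairwise two-sided
Wilcoxon rank-sum tests with Benjamini–Hochberg (BH) correction and the
usual star thresholds (0.05 / 0.01 / 0.001). The rank-sum test is exact
when both groups have <= 25 cells and no ties, and uses the tie-corrected
normal approximation otherwise; at single-cell group sizes the
approximation is the operative branch.

## Marker (DEG) selection

Upregulated one-vs-rest markers per cell type: two-sided Wilcoxon rank-sum
per gene (tie-corrected normal approximation; constant genes get p = 1), BH
across genes within the focal type, and gates

* q <= alpha (default 0.05),
* log2 fold-change of mean normalized expression, pseudocount 1, >= 0.25,
* in `"specific"` mode only: detection-fraction difference
  (focal − rest) >= `min_diff_pct` (default 0.25).

These defaults emulate the de-facto standard single-cell marker workflow;
only `min_diff_pct` is prescribed by the analysis this package reproduces,
the rest are recorded here as the package's own convention. BH within the
focal type (rather than pooled across types) keeps each one-vs-rest screen
self-contained.

## Phylostratum profiles

Mean expression per (ps, cell type) uses two-stage averaging — per-cell
mean over the stratum's genes, then mean over the type's cells — so every
cell contributes equally regardless of library size; the pooled alternative
would weight cells by depth. Relative expression rescales each ps row to
[0, 1] across cell types (min–max). Constant rows are reported missing with
a warning rather than 0 or 0.5: a flat profile carries no ranking
information. A stratum with no surviving genes is likewise missing, not
zero. Per-ps cross-type comparisons use pairwise Wilcoxon tests with BH
applied across the entire (ps × pair) table, the conservative choice.

The shared/unique ("Venn") partition calls a gene expressed in a type when
it is detected in >= `detect_frac` (default 0.10) of the type's cells — a
threshold the upstream description leaves open; it is exposed in the config
and the partition identity (regions sum to the union, per ps) holds for any
value.

## Enrichment of DEGs across phylostrata

For each cell type, the test set is its DEG list and the background is the
union of DEG sets over user-chosen background types (a gene DE in several
background types counts once; the focal type's own DEGs belong to the
background when it is listed there, and any test genes outside the
background are unioned in so the margins are consistent). For stratum j
with k test genes of K background genes among n test and N background:

* p-value: two-sided hypergeometric by the minimum-likelihood rule — the
  total probability of outcomes no more likely than k, with 1e-7 relative
  slack for floating-point ties (the convention of standard exact-test
  implementations; tail-doubling is not used);
* effect size: log2 odds ratio of (in-ps vs not) × (test vs rest of
  background) with Haldane–Anscombe 0.5 pseudocounts, finite at k = 0 and
  k = n; zero means the observed frequency equals the background
  expectation;
* BH across all (cell type, ps) cells.

The implementation enumerates the hypergeometric support directly; tests
check it against exact-integer enumeration for every margin with N <= 60
and against an independent exact-test implementation.

## Synthetic data

The generator emulates the statistical structure the analysis assumes, not
any particular tissue: genes laid out over 22 strata; negative-binomial
counts (Gamma–Poisson, dispersion 2, variance μ + μ²/θ); log-normal
library-size variation (σ = 0.35) so normalization is non-trivial;
mitochondrial genes (`mt-` prefix, assigned ps 1) at ~5% of counts; and
per-type marker programs that multiply the NB mean of designated-stratum
marker genes by a fold factor. A small fraction of cells is emitted damaged
(2% with 8× mitochondrial content) or shallow (2% at 2% library size) so QC
has work to do, and 1% of genes carry no age, exercising the discard path.

The reference design plants the study's qualitative structure: an ancestral
chondrocyte-like type (IC: 200 markers from ps 1–4), an osteoblast-like
type (OB: 100 markers from ps 11), and a hypertrophic-chondrocyte-like type
(HC: 240 markers from ps 11–12), 100 cells each, fold 8, 250 genes per
stratum, base NB mean 0.3 (≈1,300 detected genes per cell, inside the QC
window). `generate_hit_table` emits a homology table consistent with the
planted ages — self-hit, an anchor hit at exactly the planted stratum,
younger-stratum extras, and above-threshold decoy hits at older strata —
so age assignment must recover the truth exactly.

What passing simulation tests does and does not show: they demonstrate
internal correctness (formulas, identities, calibration, power against
planted effects) under NB noise with independent genes. Real data add gene–
gene correlation, batch structure, doublets and ambient RNA, none of which
the generator models; conclusions about real tissues still require the real
matrices.

## Calibration and power checks (problem sizes used)

* Type-I error: 200 null replicates (3 exchangeable types × 25 cells,
  440 genes) keep the raw pairwise TAI false-positive rate near 5%, and 200
  null enrichment replicates (test set drawn uniformly from a 400-gene
  background) stay below 5% — the discrete hypergeometric is conservative.
* Power: in 100 replicates of the reference design, the young-program type
  exceeds the ancestral type's median TAI with q <= 0.05 and shows ps-12
  enrichment (q <= 0.05, log-odds > 0) in >= 95% of seeds.
* Oracle equivalence: vectorized TAI / pTAI / per-ps means match naive
  loops to 1e-12 relative on 50-gene × 20-cell instances; the two-sided
  hypergeometric matches exact-integer enumeration for all ~6.4e5 tables
  with N <= 60.

These sizes were chosen to make the checks sharp at desk scale; all of them
are recomputed from scratch by `scripts/acceptance.py`.

## Pipeline

`run_pipeline` executes ages → load → QC → normalize → DEGs → TAI/pTAI
(full, DEG-restricted, and downsampled to n = 50/100 cells per type) →
profiles → Venn → enrichment, communicating through TSV/MatrixMarket files
so every stage can be audited or re-run alone. The manifest records
versions, parameters, the seed, and stage-by-stage cell/gene/DEG counts;
re-running the same config is bit-identical. Config validation (threshold
ranges, file existence) happens before any stage runs, and stage failures
abort with the stage name.

## Known limitations

* Gene ages are only as good as the hit table; the package cannot detect
  homology the upstream search missed (young-biased error is inherent to
  the approach).
* The Wilcoxon asymptotic branch is approximate for heavily tied small
  groups; exact p-values are available only for groups <= 25 without ties.
* The DEG defaults beyond `min_diff_pct` are conventions, not ground truth;
  downstream enrichment inherits any marker-selection bias.
* The simulator draws genes independently; correlation-sensitive behavior
  (e.g. co-expression modules concentrated in one stratum) is untested.
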