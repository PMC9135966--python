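# Methods

`citeflow` re-implements, as a tested library, a CITE-seq cohort analysis
for a two-group (ankylosing spondylitis vs healthy) PBMC study: quality
control, normalization, cell-type-scoped differential expression of genes
and surface proteins, compositional and subcluster testing, gene-set
over-representation, and subject-level machine-learning classification.
Because the full deposited cohort cannot be assumed at hand, a synthetic
cohort generator with planted ground truth is a first-class module; every
downstream stage is validated against what the generator planted.

## Synthetic cohorts (`citeflow.simdata`)

The generator emulates the structure the analysis assumes:

* **Cohort shape.** Defaults: 29 healthy and 10 AS subjects, assigned
  round-robin to 3 sequencing batches, 200 cells per subject, 500 genes
  (10 mitochondrial `MT-*`, 40 ribosomal `RPS*`/`RPL*`), a 30-tag ADT
  panel including 9 isotype controls.  The gene/tag panels and per-subject
  cell counts are desk-scale stand-ins for a real 10x experiment
  (~20k genes, ~2,500 cells/subject); all are configurable.
* **Counts.** RNA counts are negative binomial via a Gamma–Poisson
  mixture: `mu = libsize × p(type, gene) × batch factor × planted cohort
  effect`, renormalized per cell; the per-gene dispersion θ (NB "size") is
  log-uniform on (5, 50) by default, matching the DE model's assumption so
  calibration tests are meaningful.  Library sizes are log-normal
  (median 2,500 UMIs, sd 0.3 on the log scale) and clipped into the QC
  window for non-outlier cells.
* **Cell types and composition.** Each type has a log-normal per-gene
  expression profile; mitochondrial/ribosomal mass fractions are pinned
  (6% / 30%) so QC percentages sit in a realistic range.  Per-subject
  mixtures are Dirichlet around the cohort weights (concentration 150);
  cohort composition shifts are planted as log-odds offsets before the
  softmax.
* **ADT.** Marker tags follow per-type profiles with NB noise plus a
  uniform nonspecific background of 0–2 counts per tag; isotype controls
  receive background only, which puts the isotype share of a normal cell
  near 0.7% (below the 2% QC cap by a wide margin).
* **Batch artifacts.** Batch effects are multiplicative per-gene
  log-normal factors (sd 0.15) shared within a batch; one designated gene
  per batch is inflated 10× to exercise the batch-artifact filter.
  Subjects can optionally be assigned to batches in cohort-contiguous
  blocks to confound batch with cohort for negative-control tests.
* **Planted truth.** Differential effects (cell type × feature × modality
  × log2 effect), composition shifts, subcluster membership (marker-
  overexpressing subset of a parent type, sampled with an AS enrichment
  factor), QC-violating cells (per rule, with parameters adjusted so only
  the planted rule is violated), and doublets (feature-wise sums of two
  cells) are all recorded in a `SimTruth`.

What the generator does **not** emulate: gene–gene correlation beyond
cell-type structure, ambient RNA, UMI saturation, batch-specific capture
chemistry, or subject-level expression random effects.  Passing recovery
tests on this generator therefore shows the pipeline implements its
contracts, not that it overcomes every pathology of real data; in
particular, cell-level DE tests on real cohorts pseudoreplicate within
subjects, a known caveat reproduced here deliberately.

## Quality control (`citeflow.qc`)

Cells are retained when total RNA UMIs ∈ [500, 10,000] (inclusive),
detected genes ≥ 200, percent mitochondrial ≤ 15%, percent ribosomal
≤ 60%, detected ADT features ≤ 260 and percent isotype counts
strictly < 2%.  Mixed operators are intentional and preserved.  Cells in
RNA-only libraries are exempt from the ADT rules rather than auto-failed.
Removal is attributed to the first failing rule in the threshold order
above, making reports deterministic.  Feature QC removes genes with zero
total count, the 9 isotype tags, and a caller-supplied ADT exclusion list
(the real panel's problematic tags live in supplementary material, so the
artifact takes the list as input).  Percent-ribosomal uses the RPS/RPL
name-prefix convention.

## Normalization (`citeflow.normalize`)

* **RNA (`vst_residuals`).** A regularized NB Pearson-residual transform:
  per gene, Poisson IRLS of counts on log10 total UMIs; per-gene
  dispersion by method of moments, then regularized by Gaussian-kernel
  smoothing of log10 θ against log10 gene mean (Silverman bandwidth);
  residuals `(x − μ)/sqrt(μ + μ²/θ)` clipped to ±√n_cells.  This is a
  single-predictor approximation to the published variance-stabilizing
  estimator; its contract — unit residual variance on Poisson-like data —
  is what the tests enforce (tolerance 0.2 at 5,000 cells).  "Corrected
  counts" (expected counts at the median library size, reconstructed
  through the clipped residuals, rounded, floored at 0) feed the
  count-based DE test.
* **ADT (`clr_normalize`).** Classic centered log-ratio per cell:
  `ln(x+1) − mean ln(x+1)` across tags.  Chosen over the per-feature
  variant some toolkits use because the per-cell composition closure
  (rows sum to 0) is analytically testable; the pseudocount is a dialect
  flag.
* Total counts and detected features are regressed out per feature by OLS
  after the transform (the analog of regressing them inside the model),
  then features are centered and unit-scaled (n−1 denominator;
  zero-variance features map to 0).
* **Subject profiles (`subject_profile`).** For the leakage check, an
  alternative per-subject normalization:
  `ln(feature counts / subject total × scale)`, with scale 10⁷ for RNA and
  5×10⁵ for ADT (near the maximum per-subject totals of the full-scale
  study).  A pseudocount of 1 is applied to zero feature sums only, so
  values for nonzero counts follow the formula exactly.

## Differential expression (`citeflow.diffexpr`)

Within each cell type, genes are tested on corrected counts with a
negative-binomial log-linear model: cohort indicator plus log10 total
counts and log10 detected features, per-gene ML dispersion (Newton on
log θ, method-of-moments start and fallback), two-sided Wald test on the
cohort coefficient.  Corrected counts rather than residuals are used
because an NB likelihood requires counts; raw counts are accepted as an
alternative input.  The fit is a batched IRLS across genes (shared design
matrix, stacked per-gene normal equations), which keeps hundred-replicate
calibration runs tractable on one CPU; agreement with per-gene
`statsmodels` fits and with a brute-force likelihood-ratio oracle is
covered by tests.

The effect size is log2 fold change of group means with a pseudo-mean of
1; base 2 follows the plotted thresholds.  Proteins are tested with the
Wilcoxon rank-sum on centered/scaled CLR values, effect = difference of
group means.  Both families are Bonferroni-adjusted within cell type ×
modality; a hit is significant when adjusted p < 0.05 and |effect| ≥ 0.20.

**Batch-artifact filter.** The qualitative rule "clear overexpression in a
small subset of batches" is quantified as leave-one-dominant-batch-out
robustness: for each significant hit, drop the batch with the highest mean
expression of that feature and re-test; hits that lose either the effect
gate or adjusted significance are flagged and withdrawn.  This is
conservative, reproducible, and catches the constructed one-batch
artifact by design.  When removing the dominant batch leaves only one
cohort, no refit is possible and the hit is left unflagged — fully
batch-confounded designs are outside what any within-dataset filter can
rescue.

## Composition and subclusters (`citeflow.composition`, `citeflow.cluster`)

Per-subject cell-type fractions are compared across cohorts with the
two-sided Wilcoxon rank-sum test: exact null distribution when
min(n₁, n₂) ≤ 10 and the data are untied, tie-corrected normal
approximation otherwise.  Results are reported unadjusted across types,
mirroring per-type reporting of composition results.

Intra-type clustering: top variable features by median of within-batch
variance ranks (default 3,000, clamped to the panel); per-batch
standardization of each feature (a deliberate simplification of
anchor-based integration whose testable contract — batch not separable in
the embedding by a linear probe — is what the tests enforce); PCA (top 30
components, deterministic SVD with a largest-loading-positive sign
convention); shared-nearest-neighbor graph (k = 20 Euclidean neighbors,
Jaccard edge weights, prune ≤ 1/15 — conventional defaults, exposed in
config, since the upstream toolkit's values are not stated); Louvain
modularity at resolution 0.6 with a seeded generator and size-sorted
labels, making clustering exactly reproducible.  Cluster
overrepresentation re-uses the composition test on each subject's
within-parent-type cluster fractions.

## Enrichment (`citeflow.enrich`)

Over-representation of significant gene lists against user-supplied GMT
collections: upper-tail hypergeometric p against a declared background
(default: all genes tested for DE in that cell type — the testing
universe), Benjamini–Hochberg within each collection.  Live database
queries and proprietary multiple-testing schemes are out of scope.

## Classification (`citeflow.mlpipe`)

Subject features are pseudobulk means of scaled expression of each
significant DE feature over the subject's cells of the corresponding
type; subjects lacking cells of a type are imputed with the
training-cohort mean.  Subjects split 50:50 stratified by cohort, ceiling
to training (29/10 → 15+5 train, 14+5 test).  Ensemble feature selection
averages normalized per-feature importances from four selectors: forward
and backward stepwise logistic selection (CV-accuracy scored), recursive
feature elimination with a random forest, and permutation importances of
a radial-kernel SVM and a small neural network (ROC-AUC scored, so
importances stay graded at small n).  Ties break lexicographically; a
selector that fails on degenerate input is dropped with a warning.  The
aggregation (mean of normalized importances) is this package's
deterministic re-specification of ensemble selection, since the cited
method's internals are not published in the source material.

The default roster spans linear, non-linear and ensemble families:
regularized logistic regression, LDA, elastic-net logistic regression,
k-NN, decision tree, random forest (20 trees; depth grid
{50, 80, 100, 150, 300}, impurity decrease {0, 0.02, 0.1, 0.5}, leaf size
1–10), gradient boosting, radial SVM (cost/γ grid), Gaussian naive Bayes,
and an averaged small neural network (bagged MLPs, size/decay grid) —
nine by default, config-swappable.  Hyperparameters are tuned by repeated
stratified CV (5-fold × 2; 10-fold × 10 selectable) on training subjects
only.  Held-out metrics: accuracy, sensitivity (AS positive),
specificity, F1, Cohen's kappa (the reading of "balanced accuracy
(kappa)"), and AUROC computed as pairwise concordance with ties counting
one half (tested identical to the normalized Mann–Whitney U).  Nothing
fitted — imputation means, scalers, selectors, grids — sees test
subjects.

## Reproducibility and problem sizes

A single master seed fans out to per-stage seeds by CRC32 of the stage
name, so stages are independently reproducible; identical config and seed
give identical manifests, and the CLI subcommands write/read the same
work-directory layout as the end-to-end runner, so both paths produce
identical outputs by construction.

The packaged validation runs use desk-scale sizes chosen to keep a full
calibration honest on a single CPU: the null-calibration study uses 100
replicate cohorts of ~500 genes and two groups of ~200 cells; the
end-to-end classification study uses the default 39-subject cohort at 200
cells per subject with 12 RNA and 6 ADT planted effects (|log2| ≥ 1)
across four cell types, repeated over 5 pipeline seeds.  Known
limitations: desk-scale panels make Bonferroni families small relative to
a real transcriptome; the cell-level DE test ignores within-subject
correlation; and the simplified integration step handles multiplicative
batch structure only.
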