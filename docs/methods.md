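# Methods

This note records the statistical models implemented in `esoatlas`, the
defaults and why they were chosen, what the synthetic atlas does and does
not emulate, and the numerical decisions taken where the design was open.

## The data model

The substrate is a cells × genes sparse UMI count matrix with per-cell
labels (barcode, sample, cell type) and a per-sample covariate table
(donor, condition ∈ {healthy, remission, active}, region ∈ {distal,
proximal, mixed}, 10x chemistry ∈ {v2, v3, v3-dual}, steroid and diet
flags, eosinophils/HPF, EREFS). In memory this is an `AnnData` plus a
pandas DataFrame; on disk it is Matrix Market (`matrix.mtx`, genes × cells,
integer) with `genes.tsv`, `barcodes.tsv`, `cells.csv`, and `samples.csv`.

## Quality control and normalization

Cells are retained when total UMIs exceed 500 (strictly) and the
mitochondrial UMI fraction is strictly below 25 % for v2 chemistry or 40 %
for v3/v3-dual — v3 libraries systematically carry more mitochondrial
reads, so a common threshold would bias retention by batch. Mitochondrial
genes are recognized by the `MT-` name prefix (configurable). Both cutoffs
read the inequality literally; boundary cells appear in the retention log.

Per-cell normalization is log(TP10K+1): `ln(1 + 10⁴ · c_g / C)` for count
`c_g` in a cell with `C` total UMIs. Pseudo-bulk aggregation has two
variants: the *sum* variant pools raw counts over a cell set and applies
the same transform to the pooled vector (used for exploratory PCA of
subset profiles), and the *mean* variant averages raw counts per gene
(used for risk-gene modules). Whether the mean variant should instead
average normalized values is not determinable from its usual description;
raw counts are the default and the alternative is exposed as an option.

## Differential cell-type abundance

For each cell type `c`, cell counts across biopsies follow a negative
binomial regression

    y_sc ~ NB(μ_sc, θ_c),   log μ_sc = x_s'β_c + log N_s,

with the biopsy's total analyzed cells `N_s` as offset — exact under the
generator's multinomial sampling of cells given depth — and condition
(treatment-coded, healthy reference), chemistry, steroid, and region as
covariates. The reported test is the Wald test of the active-vs-healthy
coefficient; remission contrasts are emitted alongside. BH FDR is applied
across cell types, with significance tiers at FDR < 0.05 / 0.01 / 0.001.

Two small-sample calibration choices matter at n ≈ 30–40 biopsies:

- **Dispersion.** `θ_c` is estimated by Cox–Reid adjusted profile maximum
  likelihood (the profile log-likelihood penalized by half the
  log-determinant of the weighted information, as in edgeR). The
  unadjusted MLE is biased downward at this sample size, which makes Wald
  tests measurably liberal (type-I ≈ 0.075 instead of 0.05 in our null
  simulations); the adjustment restores ≈ 0.05. A Poisson GLM is the
  fallback when the NB fit fails or the dispersion pins at zero, flagged
  in the output.
- **Reference distribution.** Wald statistics are referred to a t
  distribution on `n − p` degrees of freedom rather than the normal, for
  the same reason; confidence intervals use the matching t quantile.

Cell types with zero counts everywhere are excluded with a warning;
constant or collinear design columns are dropped with a warning.

The rank-based alternative quantile-normalizes each cell type's proportion
vector across samples to a common reference distribution (the mean of the
order statistics across cell types, average-rank ties), then fits OLS on
the same covariates with two-tailed t tests. In paired simulations it is
consistent with the NB model with equal or slightly lower power.

## CLR, PCA, PERMANOVA

Zero counts are imputed with 0.5 (half-count multiplicative replacement —
exposed as a parameter), rows closed to proportions, and the centered
log-ratio taken; rows sum to zero and the transform is invariant to
rescaling a sample's counts. PCA is centered SVD with a fixed sign
convention (the largest-|loading| cell type of each component is positive).

PERMANOVA partitions the Gower-centered squared Euclidean distance matrix
of quantile-normalized composition rows by sequential (Type I) sums of
squares over the model terms, using projection matrices exactly as in
distance-based redundancy analysis; per-term pseudo-F is tested by
permuting samples with `p = (1 + #{F_perm ≥ F_obs}) / (1 + n_perm)` —
unbiasedly conservative. The default `n_perm = 9999` resolves p down to
10⁻⁴ at interactive cost; the implementation is checked in the test suite
against scikit-bio (one-way) and vegan's `adonis2` (sequential,
multi-term), matching both to 8+ digits.

## Differential expression and the ambient filter

Per cell type and per gene (prefiltered to ≥ 10 % expressing cells in
either group, groups of ≥ 20 cells), a logistic regression of group
membership on the gene's log(TP10K+1) expression plus log2 detected genes,
steroid, region, and chemistry is compared against the covariate-only null
by a likelihood-ratio test (χ², 1 df). Bonferroni and BH adjustments are
both emitted; the headline "significant" call is Bonferroni-adjusted
p < 0.001 *and* fold change > 1.5. Fold change is the ratio of group means
of `expm1(lognorm)` with a 10⁻⁹ pseudocount — linear in the underlying
TP10K scale, so label swaps negate log2FC exactly.

Ambient-RNA artifacts inflate expression of genes from abundant
neighboring cell types. The filter: for each upregulated gene, compare its
mean expression in the focal cell type *per focal-condition sample*
against the pooled comparison-condition cells of the same type; if
strictly more than half of the M focal samples are below the baseline, the
pooled up-call is driven by a contaminated minority and the gene is
flagged (ties retain; samples with zero cells of the type are excluded
from M with a warning; the majority threshold is a parameter). The
per-sample check is a sign-of-means comparison by default; a per-sample
test variant is exposed through the same interface.

## Ligand–receptor interaction scoring

For gene `g` and subset `s`, the share `s_g` is the fraction of `g`'s raw
UMIs in `s` (cells are the aggregation unit; subsets under 10 cells are
excluded as share noise). A complex of `m` subunits has weight
`(∏ s_g)^(1/m)` — zero if any subunit is absent. The directed score of a
ligand→receptor pair for subsets (i, j) is the ligand weight in `i` times
the receptor weight in `j`, and the interaction strength is the sum of the
top k = 10 pair scores, damping the long tail of weak background pairs.
Partner rankings are reported with row z-scores (population SD; a single
or all-equal row is flagged and scored 0). Conditions are analyzed
separately by recomputing shares within each condition's cells. Direction
is primary (i supplies the ligand); the symmetrized sum of both directions
is exported as well. Autocrine (i = j) interactions are included.

## Reference mapping

Preprocessing on the labeled reference: log(TP10K+1), selection of the
2000 most variable genes (or all genes if fewer), per-gene
standardization. The frozen statistics are re-applied unchanged to any
query — no leakage, bit-stable. Neighborhood component analysis (PCA
initialization, fixed seed, ≤ 200 iterations) learns a linear map to a
50-dimensional latent space; for tractability the NCA objective is
optimized on a per-class subsample (default 150 cells/class) and the
learned map applied to everything. Query cells get the majority label of
their k = 11 Euclidean nearest reference cells, ties broken by summed
inverse distance, with the vote fraction as confidence (< 0.5 flagged
uncertain). Queries must share ≥ 50 % of the model's genes.

## Signatures, programs, risk modules

Signature scores follow the binned-control scheme: genes are ranked by
dataset-mean expression into 25 bins; each signature gene draws 100
control genes from its bin (with replacement if the bin is small); the
score is mean signature minus mean control expression per cell. Defaults
(25 bins, 100 controls) are the cited method's published defaults. The
scheme is shift-invariant and centered at zero for signatures
indistinguishable from their bins; a signature that *is* an entire bin
scores exactly zero.

NMF (coordinate descent, seeded random initialization) factorizes a cell
family's log-normalized profiles into r nonnegative programs; per-cell
scores are the program coefficients and top-loading genes describe each
program. The macrophage-style default r = 6 comes with a rank-sweep
reconstruction-error report, as no principled rank is fixed by the
analysis.

Risk-gene modules: genes expressed in ≥ 25 % of cells of at least one
subset are profiled by mean pseudo-bulk per subset, square-root
transformed (variance stabilization for counts), and clustered by Ward.D2
on Euclidean distances. The tree is cut either into an explicit number of
modules or at half the maximum merge height.

## The synthetic atlas

The generator emulates the structure of a droplet scRNA-seq atlas of
esophageal biopsies: 22 donors (8 active / 7 remission / 7 healthy), 15 of
them contributing paired distal + proximal biopsies (37 samples: 14 active
/ 11 remission / 12 healthy), chemistry batches of 7 v2 / 9 v3 / 6
v3-dual donors, clinical covariates (eosinophils/HPF high only in active
disease, EREFS, steroid/diet flags).

Per sample, the cell-type composition is Dirichlet(base ⊙ exp(condition
effects)) and per-type cell counts are multinomial. Per cell, the library
size is lognormal (median 2500, σ = 0.35) and gene counts are multinomial
given the library — so the log-total offset in the abundance model is
exactly correct. Cell-type expression profiles are independent gamma draws
per (type, gene) (shape 0.35: a few dominant genes per type, a long tail),
modified multiplicatively by planted DE effects; mitochondrial genes
(named `MT-…`) receive a per-cell Beta-distributed share centered at the
chemistry's mean (8 % v2, 16 % v3). Ambient contamination switches each
UMI to the sample's own soup — the mixture of that sample's type profiles
at its true composition — with per-sample probability either fixed or
drawn from a condition-specific Beta. Planted ligand–receptor axes (and
"exclusive" genes for contamination scenarios) concentrate chosen genes in
chosen types. One master seed drives a per-sample tree of independent
streams, so outputs are byte-identical across runs and partial
regeneration is stable.

Desk-scale defaults are 15 cell types, 300 genes, and 400 cells per sample
(≈ 15k cells) rather than the ~60 subsets and ~400k cells of a full
atlas; they keep the entire validation suite in the minutes range while
preserving every structural feature the statistics depend on. What the
generator does **not** emulate: doublets, cell-cycle structure, batch
effects beyond the chemistry-dependent mitochondrial load, spatial
(distal/proximal) expression differences, or gene–gene correlation within
a type beyond the shared profile. Passing tests therefore demonstrate
correctness of the statistical machinery under a known generative model,
not robustness to every artifact of real tissue data.

### Validation scenario design

- **Abundance recovery** uses the composition-only simulator (the same
  Dirichlet-multinomial core without per-cell expression) at n = 30
  samples: a planted log-2 concentration bump on a mid-abundance type,
  whose implied true log proportion ratio (slightly below log 2 because of
  closure) must fall inside the 95 % Wald interval in ≥ 90 % of
  replicates; matched null runs check type-I error.
- **The k-robustness check** runs on an atlas with a planted *graded*
  interaction network — each type signals to its next three neighbors
  with 4 / 2 / 1 dedicated axes — because with a structureless background
  catalog the third and fourth partner of a type have intrinsically tied
  strengths and no scorer has stable top-3 sets; real tissue (and the
  planted network) is heavy-tailed.
- **The ambient-filter scenario** plants a gene exclusive to an abundant
  neighboring type and draws per-sample contamination from a near-two-point
  Beta: most active samples clean, roughly a quarter soup-dominated. This
  is precisely the regime the majority-downregulation filter exists for — a
  contaminated minority drives a spurious pooled up-call while the majority
  of samples sit below baseline. Under uniformly moderate contamination
  there is no spurious up-call to remove, and the filter correctly stays
  silent.

## Known limitations

- The NB abundance model treats biopsies as independent; paired
  distal/proximal biopsies from one donor are handled only through the
  region covariate, not a donor random effect.
- The DE model is cell-level logistic regression; it does not account for
  pseudoreplication within samples (no mixed model), matching the method
  it re-implements.
- Interaction scores are descriptive ranks; no permutation significance is
  attached by design.
- NCA is fitted on a per-class subsample for tractability; with very
  imbalanced rare classes the projection may underweight them.
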