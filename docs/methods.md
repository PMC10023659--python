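# Methods

This note documents the models and procedures the package implements, the
parameters that matter, what the synthetic-data generator does and does not
emulate, and the numerical and design choices made where the design was
genuinely open.

## Preprocessing

**Gene filtering.** Genes are kept when CPM > 1 (raw library sizes, no
pseudocount) in at least a required number of samples. Two presets mirror
the analysis's two cohorts through one code path: ≥50% of samples
(case/control cohort) and ≥3 samples (drug cohort). The required count for a
fraction f over n samples is ⌈f·n⌉.

**TMM normalization.** Scale factors follow the trimmed mean of M-values
construction: the reference sample is the one whose 75th CPM percentile is
closest to the mean of those percentiles; per sample, gene-wise log2
expression ratios (M) and average log2 expression (A) against the reference
are double-trimmed (30% on M, 5% on A, by ranks) over genes nonzero in both
samples, and the factor is 2 to the inverse-variance-weighted mean of the
surviving M values, with the asymptotic binomial variance as weight.
Factors are rescaled to geometric mean 1. Exact factor-level agreement with
an independently coded implementation of the formula is asserted to 1e-10
in the tests.

**logCPM.** `log2((count + 0.5) / (lib·factor + 1) · 1e6)`. The 0.5
pseudocount keeps zeros finite; its residual effect on a depth-doubling is
0.5/((2c+1)·ln 2), i.e. below 1e-3 only once counts reach ~500, which is
the bound the tests assert.

**Precision weights.** Per-gene linear models on logCPM give residual
standard deviations; a lowess (span 0.5) of sqrt(residual SD) on average
log2 count is evaluated at each observation's fitted log-count (linear
interpolation, constant extrapolation) and the weight is the predicted SD
to the power −4, clipped to [1e-6, 1e6]. This is the standard
mean–variance-trend weighting for count-derived log expression.

**PCA and outliers.** PCA is the SVD of gene-centered (not scaled) logCPM;
each component is oriented so its largest-magnitude loading is positive,
making signs deterministic. Samples are flagged as outliers when their
standardized score exceeds 5 SD (3 SD in the small-cohort preset) on at
least two of the top 20 components, in a single pass with no re-fit. Note a
geometric fact the generator respects (below): a single sample displaced
along any one direction is extreme on exactly one principal component, so
the two-component rule is only triggered by samples whose deviation spans
directions in which the rest of the cohort also varies — e.g. two samples
sharing a degradation axis.

## Covariate handling

Candidate covariates are tested against the top 20 expression PCs — Pearson
correlation for continuous covariates, one-way ANOVA for categorical — and
summarized by the minimum Bonferroni-adjusted p across PCs. Selection is
greedy: add the strongest covariate if its adjusted p < 0.05, regress it
out, recompute PCs, repeat (ties break lexicographically; `recompute_pcs`
is configurable). A paper-faithful mode bypasses selection and uses the
fixed eight-term design (library batch, sex, age, effective mapping rate,
intergenic rate, RIN, PMI, pH) or the five-term small-cohort design.
Residualization is per-gene (weighted) least squares; the weighted
cross-product of residuals with every design column vanishes to 1e-8.
Missing covariate values are a hard error — no imputation.

## Differential expression and the signature score

The contrast fit is per-gene (weighted) least squares on a two-level group
indicator. With moderation on (the default), residual variances are shrunk
toward a scaled inverse-chi-square prior fitted by matching the mean and
variance of log s² (digamma/trigamma moment inversion); the t-test degrees
of freedom grow by the prior's. Genes with exactly zero residual variance
get p = 0 if the effect is nonzero and p = 1 otherwise, flagged in a
`zero_variance` column. BH adjustment is the standard step-up rule.

The signature score is the dot product of a sample's covariate-corrected
logCPM residuals with the contrast's log fold changes over all genes with
nominal p < 0.05. It is linear in the residuals, and with betas estimated
on the same samples it is circular by construction — reproduced faithfully
as the default, with the caveat documented here; the score is a
*descriptive* aggregation, and its group comparisons (below) remain valid
because all samples, cases and controls, are scored with the same fixed
beta vector.

Group comparisons follow a Shapiro–Wilk gate into non-parametric tests:
Mann–Whitney U (exact enumeration when both groups ≤ 20 and tie-free, else
normal approximation with tie and continuity corrections), Kruskal–Wallis
with tie correction (all-tied data reports H = 0, p = 1), and Dunn post-hoc
z tests with the tie-corrected rank variance, BH-adjusted across pairs
(Bonferroni available).

## Consensus co-expression modules

Signed adjacency `((1 + r)/2)^12` on Pearson correlations of
technical-covariate-residualized expression; topological overlap
`TOM_ij = (Σ_u a_iu a_uj + a_ij) / (min(k_i,k_j) + 1 − a_ij)`; the second
dataset's TOM is scaled so its 0.95 off-diagonal quantile matches the
first's, and the consensus is the element-wise minimum.

Module detection replaces the dynamic-hybrid tree cut with a transparent
procedure that keeps its semantics: recursive binary splitting of the
average-linkage dendrogram of 1 − consensus TOM, where a split is accepted
only when it runs along a real boundary — at least one piece more cohesive
within than across (ratio 1.5) *and* cross-piece similarity near the
matrix-wide background level (within 10× the median off-diagonal TOM).
The first condition stops the recursion inside homogeneous background, the
second stops it from shaving the high-connectivity core off a coherent
module. Pieces below max(10, min_size/3) are peeled off for later rescue.
All surviving clusters then enter iterative eigengene merging — the closest
pair merges while its eigengene correlation exceeds 1 − 0.25 in *both*
datasets — before any size pruning, so over-split module halves are
reunited. After pruning to the minimum size of 30, a consensus-kME stage
(analogous to the PAM stage of dynamic hybrid cutting) reassigns unassigned
genes whose minimum kME over the two datasets reaches 0.3 for some module,
and removes members below 0.3 in either dataset. Modules are relabeled
M1, M2, … by decreasing size. The published parameters — signed network,
soft power 12, minimum size 30, merge cut 0.25, minimum kME 0.3 — are used
exactly; only the cutting algorithm is the package's own.

Eigengenes are the first principal component of the module's
gene-standardized expression, unit variance, oriented so the mean member
correlation is non-negative. Eigengene–condition association is OLS on a
level indicator with two-sided t tests and BH across modules per level.
A module is **convergent** when the disease and drug t-statistics agree in
sign with both |t| ≥ 2 (≈ two-sided p < 0.05 at these sample sizes; the
threshold is explicit and configurable), **divergent** on opposite signs,
otherwise indeterminate.

## Deconvolution

Per-type profiles are CPM-normalized means over the cells of each type,
after applying the configured cluster merges and drops. Each bulk sample's
CPM vector is decomposed by non-negative least squares on the profile
matrix and renormalized to the unit simplex (identical to an
equality-constrained solve on noiseless input, and simpler). When samples
assayed on both platforms are supplied, each gene's bulk values are shifted
and scaled so their overlap-sample mean and SD match the reference-composite
values before the NNLS — a transparent "Bisque-like" moment matching; the
full probabilistic estimator of that tool is intentionally not re-derived.
All shared genes are used; no marker pre-selection. Proportion group tests
reuse the non-parametric battery with BH across cell types per test family.

## Enrichment

2×2 Fisher's exact tests conditioned on a declared background (all
expressed genes; restricted to one-to-one orthologs for module enrichment).
Two-sided p sums hypergeometric probabilities no larger than the observed
table's, which matches an enumeration oracle exactly for backgrounds ≤ 60.
Odds-ratio conventions: bc = 0 with ad > 0 → +inf; ad = 0 → 0. Sets with
fewer than 4 list hits are excluded *before* BH (this choice affects the
multiplicity denominator and favors power; the alternative order is a
one-line change). The BH family is per gene list.

## Synthetic data: what it emulates, and what it does not

Counts are negative binomial (Var = μ + αμ², default α = 0.1) with
log-uniform library sizes (1–3 million), gene baselines log2-CPM ~ N(4, 2),
per-gene random covariate coefficients on standardized covariates, a
diagnosis effect of base_lfc × subgroup multiplier on planted DE genes
(multipliers atypical 1.5 > mixed 1.2 > negative 1.0 > typical 0.8 at group
sizes 113/23/28/27/10), and per-module latent factors with loadings
0.5–1.0 × module_loading (default 1.0 log2 units per factor SD). The paired
design shares one module plan (gene membership and loadings) across both
cohorts on ortholog-matched genes, with dataset-specific factors, noise and
condition effects; condition effects default to ±0.8 SD in the 201-sample
cohort and ±2.0 SD in the 33-sample drug cohort, sizes at which eigengene
|t| comfortably exceeds 4 in both while distinct modules' factors stay
nearly uncorrelated (a large shared shift would correlate every
effect-carrying module through the condition indicator). A configurable
fraction (default 30%) of the case/control fold changes is shared, with
sign, by the drug cohort's treated groups, giving positive cross-species
t-statistic concordance.

Outliers are planted as globally distorted samples — a log-scale distortion
with a component shared between outliers and an individual component (SD 2
each) — emulating degraded tissue. A pair of such samples is extreme on at
least two principal components (the shared axis and their contrast), which
is what the two-component outlier rule requires; a lone distorted sample
defines only one extreme direction and is invisible to that rule by
construction.

The deconvolution surface simulates 2 000–10 000-count single cells around
per-type profiles with type-exclusive marker blocks (30 genes at 16× /
0.25×), and bulk mixtures whose per-sample proportions are Dirichlet
(concentration 100) around group means — controls (0.50, 0.25, 0.25) for
excitatory neurons, inhibitory neurons and astrocytes; cases (0.50, 0.20,
0.30), i.e. a planted 0.05 inhibitory-neuron decrease.

Problem sizes are deliberately scaled down from a real cohort (~18 000
expressed genes) for fast, exhaustive testing: 4 000 genes with 10%
nominally DE for signature experiments — a scale at which the planted
subgroup ordering is recovered in ≥90% of seeds, as in the much sharper
real-data separation — and ~450 genes with five planted modules of 35–55
genes for consensus-module experiments.

What the generator does **not** emulate: read-level sampling and mapping
artifacts, gene–gene correlation beyond the planted modules, non-NB
overdispersion (e.g. zero inflation), ancestry or other population
structure, batch-by-condition confounding, and cell-type proportion shifts
acting on the bulk expression of the *same* samples used for signature
scoring. Passing tests therefore demonstrate the correctness and power of
the statistical machinery under the assumed generative model, not the
field validity of the biological conclusions.

## Numerical choices and conventions

- All randomness flows from one seed through isolated SeedSequence-spawned
  streams; outputs are byte-identical across runs.
- Degenerate fits: residual variances and effects below 1e-10 of the data
  scale are treated as exactly zero before the p-value conventions apply.
- Output tables are TSV with floats at 6 significant digits; the manifest
  is sorted JSON with SHA-256 digests, so equality of manifests certifies
  equality of every output.
- PCA signs, covariate-selection ties and module labels all have
  deterministic conventions (largest-loading-positive, lexicographic,
  by decreasing size).

## Known limitations

- The signature's default circularity (betas and scores from the same
  samples) inflates case–control score separation; the leave-one-out
  refinement is not implemented — external beta tables are the supported
  clean-inference route.
- The simplified module cut is not the published dynamic-hybrid algorithm;
  on data with nested or strongly overlapping modules the partitions may
  differ even though the size/merge/kME parameters match.
- The deconvolution estimator is a transparent NNLS core, not the cited
  tool's full hierarchical model; with strong platform effects and no
  overlap samples its estimates are biased.
- Fisher's exact test is conservative at small margins (discreteness), so
  its attained type-I level sits below nominal.
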