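# Methods

This note documents the models, defaults and design choices behind
`rumengwas`, in the order the pipeline runs. It covers what each stage
assumes, which knobs matter, and where the implementation had to make a call
that the analysis style itself leaves open.

## Data model and phenotype derivation

Abundances live in an `AbundanceMatrix` (samples × contigs) with a declared
unit: raw `counts`, `cpm` (rows sum to 10⁶) or `relative` (rows sum to 1).
Absence is an explicit zero; missing values are rejected. Phenotypes are per
animal: milk yield (kg/d), dry matter intake DMI (kg/d), body weight (kg),
fat/protein %, parity, population.

* **FE** = milk yield / DMI, per animal.
* **RFI** = observed DMI − DMI expected from an ordinary least-squares
  regression fitted within each population. The default expected-intake model
  is intercept + milk yield + metabolic body weight (BW^0.75), the standard
  residual-feed-intake formulation; the predictor list is configurable.
  Residuals average zero within each population by construction and are
  orthogonal to each predictor. A rank-deficient design is a hard error
  naming the predictors; missing phenotype fields are hard errors, never
  imputed.
* **Groups**: the extreme-phenotype design labels the top *n* animals by the
  chosen trait HIGH and the bottom *n* LOW (default 15/15 of 30). Ties are
  broken by stable input order; a tie straddling a cut emits a warning.
  Assignment is idempotent.

**Prevalence filter.** Contigs observed (nonzero) in fewer than
`min_prevalence_count` samples are removed; the default is 7 of 30. The
alternative "25% of individuals" convention is available as ⌈0.25·n⌉. The
pipeline order is quantify → filter → CPM, and the filtered matrix keeps its
original CPM values — no renormalization after filtering, since nothing in
the analysis requires the filtered rows to re-sum to 10⁶.

## Information-gain pre-selection

Entropy of a contig's CPM is taken as Gaussian: H(σ) = log2(σ√(2πγ)), in
bits. The information gain is the pooled entropy minus the
group-size-weighted mean of the within-group entropies. Two numerical
decisions matter:

* **SD estimator**: maximum-likelihood (divide by N), not N−1. With ML SDs
  the pooled variance equals the within-group mixture variance plus a
  non-negative between-group term, and concavity of the log guarantees
  IG ≥ 0, matching the "entropy reduction" reading. Sample SDs are available
  via `ddof=1`.
* **The constant γ**: "Euler constant" is ambiguous between Euler–Mascheroni
  (0.5772…) and Euler's number e (the constant of the Gaussian differential
  entropy ½log(2πeσ²)). The default is Euler–Mascheroni, but the choice is
  provably irrelevant: because the conditional-entropy weights sum to one,
  the √(2πγ) term cancels identically in IG. A test asserts equality to
  1e-12 under both constants.

Degenerate contigs: zero within-group SD means the contig separates the
groups perfectly — it is flagged and ranked first with IG = +∞ rather than
dropped; a zero pooled SD (constant contig) gets IG = 0 and a flag.

Selection keeps the ⌈(1 − percentile/100)·p⌉ top-ranked contigs (default
95th percentile). The ceiling convention is the one consistent with the
printed pair 175,969 → 8,799. Boundary ties resolve by stable feature order
with a warning.

## metaGWAS

Per contig, a logistic regression of group (HIGH = 1, LOW = 0) on the
contig's CPM — intercept + slope, fitted by IRLS (statsmodels `Logit`), Wald
z test on the slope. Choices:

* **Standardization** of the predictor is on by default (recorded in the
  output); it changes the reported slope scale but not z or p.
* **Significance**: raw α = 0.05, no multiplicity correction by default —
  that is the procedure being reproduced; Benjamini–Hochberg is available
  via `correction="bh"` because thousands of tests at raw α is liberal.
* **Complete separation** (non-overlapping group ranges) is detected before
  fitting and reported as missing-with-reason; separated contigs are
  excluded from the significant set rather than pushed through a penalized
  fit, keeping the pathology visible. Constant contigs likewise.

Calibration: with Gaussian null features at n = 30 (15/15), the significant
fraction is within binomial error of α and p-values pass a KS uniformity
check. With strongly heavy-tailed (e.g. log-normal) predictors the small-n
Wald test is noticeably conservative — a property of the test worth knowing
when interpreting counts of significant contigs.

The taxonomy-level analysis fits a binomial-family GLM with logit link of a
taxon's relative abundance on efficiency group + parity and reports the group
effect; the reversed direction (group as response, abundance + parity as
predictors) is a config switch, since the underlying wording is ambiguous.
Spearman panels report rank correlations between the top-k smallest-p contigs
and the continuous traits (FE, RFI, DMI, milk yield, milk solids, body
weight).

## Clustering and multiscale-bootstrap support

Animals are clustered on the significant contigs with correlation distance
(1 − Pearson between animal profiles) and average linkage (UPGMA) — the
defaults of the standard multiscale-bootstrap clustering tooling. Euclidean
distance is a config option.

**Transform.** The pipeline clusters on log2(CPM+1), not raw CPM. Contig
baselines span orders of magnitude, so on the linear scale the Pearson
distance between animals is controlled by the one or two most abundant
contigs and group structure is easily lost; the log transform gives every
selected contig comparable leverage. The same transform (and rationale)
applies to the prediction stage below. `hcluster` itself is
transform-agnostic — the transform is an explicit pipeline choice.

**Resampling unit.** Contigs (features) are resampled; animals are
clustered. At each scale r in the default grid 0.5, 0.6, …, 1.4, each of
`b_per_scale` (default 1,000) replicates draws ⌈r·p⌉ contigs with
replacement, re-clusters the animals, and every original internal edge is
scored by whether its exact leaf set appears. Each scale has its own seeded
substream keyed by (seed, r), so BP at a given scale is independent of which
other scales are in the grid — and BP at scale 1 from a multiscale run
equals a single-scale run bit-for-bit.

**AU computation.** ψ(r) = Φ⁻¹(1 − BP_r) is fitted as v√r + c/√r by weighted
least squares with delta-method binomial weights b·φ(ψ)²/(BP(1−BP));
AU = 1 − Φ(v − c). BP values of exactly 0 or 1 are moved off the boundary
with (count + 0.5)/(b + 1) before the probit transform. An edge present in
every replicate at every scale reports AU = 1 without fitting; absent
everywhere, AU = 0 with a diagnostic flag. The conventional support
statement "cluster p-value < 0.05" corresponds to AU ≥ 0.95 here.

**Accuracy.** Cutting the tree into k clusters (k = 2 by default) and
scoring against known group labels uses the best one-to-one cluster→label
assignment (Hungarian matching on the contingency table), so accuracy is
label-permutation invariant and ≥ 1/k for balanced truth. Nested analysis:
within each FE group, animals are re-labelled HIGH/LOW on DMI by median
split, clustered on the DMI-associated contigs, and reported with composite
labels (H-Hdmi etc.); subgroups under 3 animals are skipped with a warning.

PCA scores are column-centered SVD coordinates with the sign convention that
each component's largest-magnitude loading is positive.

## Prediction and the random-contig null

The linear model y = y₀ + xβ + e is fitted by minimizing
½‖y − Xβ‖² + nλ‖β‖₁ (n = training size) with cyclic coordinate descent on
z-standardized features. Numerical details:

* Gram-matrix (covariance) coordinate updates; glmnet-style warm starts down
  a short geometric path from λ_max for single fits, and a full warm-started
  path inside cross-validation.
* Convergence for final fits: largest coefficient change per sweep < 1e-8.
  Inside CV paths, where p > n and correlated columns can make the
  coefficient split wander while the fit is converged, the criterion is the
  largest per-coordinate change in fitted values < 1e-7·‖y‖².
* Verified properties: monotone objective decrease (asserted in debug mode),
  KKT conditions at convergence (|x_jᵀr| ≤ nλ + 1e-6 for inactive, equality
  within 1e-6 for active coefficients), soft-threshold equivalence on
  orthonormal designs, and exact-zero solutions at λ ≥ λ_max.
* λ is selected by 5-fold CV on a log grid from λ_max down four decades
  (minimum mean out-of-fold squared error), the only principled default when
  no value is stated; a fixed λ can be passed through instead.

**Predictors are log2(CPM+1)**, as in the clustering stage. Beyond scale
dominance, the cross-population argument matters here: baseline abundance
shifts between herds under different diets are roughly multiplicative on
CPM, hence additive and bounded on log-CPM, so coefficients learned in the
reference herd transfer. Validation features are matched by contig id;
contigs missing from the validation matrix are zero-filled with a logged
mapped fraction. Standardization parameters come from training only.

Accuracy is the Pearson correlation between predicted and observed
phenotypes. The null distribution refits the model (same λ strategy) on
random contig subsets of the same size drawn uniformly without replacement
from the full post-prevalence-filter universe — deliberately not from the
IG-pre-selected pool, since the contrast of interest is "selected contigs
vs generic contigs". Replicates whose CV-selected model shrinks to the
intercept have no defined correlation; they are reported (`n_undefined`) and
excluded from the summary statistics. The observed accuracy's percentile
rank is the fraction of defined replicate accuracies at or below it.

Default subset sizes, when emulating the published analyses, are the number
of significant contigs for the trait (the source reports 422 for FE and 619
for DMI in its Results text; its figure caption says 448/523 with a
different threshold — the counts are configurable and the pipeline defaults
to its own significant-contig count).

## Synthetic cohorts

The generator produces a reference herd (default 30 animals, latent 15/15
HIGH/LOW classes) and a validation herd (31 animals) over a shared contig
universe (2,000 by default; real studies are ~100× larger — the sizes here
keep the full pipeline in seconds while preserving the n≪p regime).

* **Counts**: each animal has log-normal baseline intensities per contig
  (log-mean ~ N(1.0, 1.5²), per-animal log-noise SD 0.5), multiplied by
  Gamma(1/d, d) factors (dispersion d = 0.3) and drawn multinomially at a
  uniform library size in [200k, 500k] — compositional, overdispersed, with
  rows summing exactly to the drawn library size.
* **Planted signal**: 50 FE-linked and 50 intake-linked contigs get a
  log-intensity shift of ±effect_size standardized units between latent
  classes, where the standardization is against the *total* log-scale SD
  (Gaussian noise plus the log-gamma variance trigamma(1/d)), so
  effect_size = 1.5 means a realized 1.5-SD separation on log-abundance.
* **Phenotypes**: FE = base 1.25 ± 0.08 by latent class plus N(0, 0.0625)
  noise — calibrated so the extreme-group assignment agrees with the latent
  class ~90% per animal, because real groups are phenotype-derived, not
  noiseless. DMI is generated analogously from its own independent latent
  class (base 20 ± 1 kg/d, noise SD 0.8). Milk yield is FE·DMI.
* **Cross-population structure**: validation baselines are the reference
  baselines perturbed by N(0, 0.3) on the log scale (a different
  diet/environment); only `shared_fraction` (default 0.6) of the FE-linked
  contigs keep their effect; 85% of contigs are mappable in the validation
  herd, mirroring partial cross-population mapping.

What the generator does **not** emulate: real taxonomic correlation
structure between contigs (contigs are conditionally independent given the
latent class), sequencing-depth-dependent noise beyond the multinomial,
lactation-stage or batch covariates, and genuine biological pathway
structure. Passing tests on these cohorts therefore demonstrate that the
statistical machinery recovers planted signal under realistic sparsity,
compositionality and noise — not that any particular biological claim
transfers to real rumen data.

## Reproducibility

Every pipeline run derives named per-stage seeds (simulate, bootstrap,
lambda_cv, null) from one root seed via `SeedSequence.spawn`, records them in
the run manifest together with the config snapshot and the per-stage feature
funnel, and is byte-identical on rerun. The bootstrap additionally keys each
scale's stream by (seed, scale) so per-scale results are grid-independent.

## Problem sizes in the shipped checks

The test-suite and acceptance-script runs use the default synthetic
conditions (2,000 contigs, 30+31 animals) with 200–300 bootstrap replicates
per scale and 200 null replicates; the full-size support computation
(10 scales × 1,000 replicates on 30 × 400) is exercised once. These sizes
were chosen so a complete run stays in the minutes range on a single core
while keeping every statistical property it checks (n ≪ p selection, AU
extrapolation over 10 scales, CV-based λ selection in every null replicate)
at its real operating point.

## Known limitations

* The AU extrapolation inherits the usual small-b instability for edges with
  BP near 0 or 1 at every scale; the continuity correction bounds but does
  not remove it.
* At n = 30 training animals, CV-selected λ is noisy; ~10–40% of random-null
  replicates can shrink to the intercept, and cross-population accuracy for
  a noisy ratio trait like FE varies widely across simulation seeds — which
  is precisely the regime the published analyses operate in.
* The logistic Wald test is conservative for strongly heavy-tailed
  predictors at this sample size; likelihood-ratio tests are not currently
  implemented.
* `taxa_association`'s binomial GLM treats relative abundances as
  quasi-binomial proportions; counts are not carried through to a proper
  binomial likelihood.
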