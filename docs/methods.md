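# Methods

## The analysis in brief

Two repetitive-element methylation markers — LINE-1 (mean of 4 CpG
positions) and AluYb8 (mean of 5), both on a 0–100% scale — are treated as
surrogates of global placental DNA methylation. The pipeline asks three
questions: (1) do the markers predict birth weight percentile after
adjustment for demographic covariates; (2) is marker methylation associated
with the methylation of coherent *classes* of array CpG loci, where classes
are defined either by a model-based clustering or by genomic attributes;
(3) which transcription-factor binding-site neighbourhoods are enriched
among marker-associated loci.

## Synthetic cohort generator

The real cohort was never deposited, so the generator is a first-class
module whose defaults *are* the study conditions, calibrated to the printed
descriptive statistics.

**Markers.** (LINE-1, AluYb8) are bivariate normal on the percent scale
with means (51.7, 65.0), SDs (4.6, 3.3) and correlation 0.29, clipped to
[0, 100] (clipping is astronomically rare at these parameters). Binary
covariates are independent Bernoulli draws at the cohort prevalences
(male 190/380, Caucasian 217/380, tobacco 36/380, alcohol 3/380, vitamins
314/380). Maternal age, BMI and gestational age are clipped normals with
desk-realistic parameters (29.5 ± 4.5 y, 26 ± 5.5 kg/m², 277 ± 8 d); they
carry no effect by default and exist so the adjusted model has real
covariates to adjust for.

**Outcome.** Birth weight percentile = 50 + linear predictor + N(0, σ²),
clipped to [0.1, 99.9]. Two deliberate design choices:

- *Marginal vs structural effects.* The configured marker effects (9.7 and
  14.5 percentile points per 10% methylation) are the coefficients a
  *single-marker* adjusted model should recover — that is how such models
  are reported. Because the markers are correlated, plugging those numbers
  in as joint structural coefficients would inflate each single-marker fit
  by the omitted-marker term. The generator therefore inverts the 2×2
  omitted-variable system, using structural coefficients (≈ 7.30, 11.55 at
  the default correlation) whose implied marginals equal the configured
  values.
- *Truncation attenuation.* Clipping the outcome flattens conditional means
  near the bounds and shrinks every fitted slope by κ = 2Φ(49.9/√(σ²+τ²))−1,
  the average probability of an unclipped draw (τ² = variance of the linear
  predictor; κ ≈ 0.939 at defaults). All configured slopes are pre-divided
  by κ so that fitted models recover them in expectation (verified to
  within 0.1 percentile points over 400 simulations).

**Residual SD.** The source study does not print it. σ = 25 percentile
points was chosen once so that the marker-coefficient CI widths are
comparable to the published ones (≈ 11 vs ≈ 14 points for LINE-1) while
keeping outcome truncation mild. It is a package choice, not a published
value.

**Beta matrix.** Each locus belongs to one of 16 latent classes; its
β-values across subjects are iid Beta(a_k, b_k). Class means form a dyadic
ladder on the logit scale (half-gaps 1.8, 0.8, 0.4, 0.22 around −2.06):
each level of a depth-4 binary hierarchy is separated by more than the span
of the levels beneath it, so the classes are genuinely recoverable by
recursive bipartition, and the equal-weight mean methylation is 0.238, the
array-wide scale of promoter-heavy platforms. Class concentrations follow
c_k = 1/(s² m_k(1−m_k)) with s = 0.3 — approximately constant logit-scale
(M-value) spread, the standard homoscedasticity assumption for methylation
arrays. A constant-concentration variant was tried first and rejected: it
makes the low-methylation tail classes much less separable than mid-range
ones, so the generator would not deliver the separability its contract
promises.

**Annotation.** Per-locus CGI / PcG / TFBS flags at configurable marginal
frequencies (defaults 0.70 / 0.12 / 0.50), a one-of repeat overlap
(Alu 0.08, LINE-1 0.06, LINE-2 0.04, MIR 0.03, else none), and, for
TFBS-proximal loci, 1–5 factor identities from a pool of 258. Frequencies
may be overridden per latent class (e.g. to enrich CGI or PcG loci in a
chosen class). Cohort, matrix and annotation use purpose-keyed RNG streams
derived from one seed, so they are jointly reproducible but mutually
independent.

**What the generator does not emulate:** probe-level intensity noise,
bisulfite-conversion failure, batch/chip effects, locus–locus correlation
within a class beyond class membership, any true marker→class-methylation
association (so omnibus results on default data are null draws), and any
true TFBS enrichment signal. Passing tests therefore demonstrate
calibration, error control and recovery of planted structure — not that the
biological associations would be re-detected in real data.

## Recursively partitioned beta-mixture clustering

Loci are items; subjects are feature columns. Each mixture component has an
independent beta density per subject, so a component is a methylation
profile with per-subject shape pairs.

- **EM.** Weighted EM with responsibilities from products of per-subject
  beta densities. The M-step starts from closed-form method-of-moments
  shapes and refines them by damped Newton steps on the weighted per-subject
  likelihood (sufficient statistics Σw·ln x and Σw·ln(1−x)); a final
  elementwise guard keeps whichever of {Newton, moments, previous iterate}
  scores the highest expected complete-data log-likelihood. The guard makes
  the observed log-likelihood nondecreasing across iterations, which the
  tests assert. Convergence at relative log-likelihood change < 1e−6, max
  500 iterations; β clipped to [1e−4, 1−1e−4] before likelihood evaluation;
  shapes clipped to [1e−2, 1e6].
- **Initialization.** Deterministic: candidate nodes split at the weighted
  median of locus mean methylation (rank-halves if degenerate). No random
  restarts, so a fit is a pure function of the data.
- **Split acceptance.** A node splits iff the 2-component BIC beats the
  1-component BIC, with parameter counts 2·S (unsplit) vs 4·S + 1 (split,
  including the mixing weight) against the node's effective locus count.
  A component collapsing below mixing weight 1e−3 is reported as degenerate
  and the node stays unsplit.
- **Pruning and labels.** Recursion stops after four accepted levels
  (≤ 16 terminal classes). Loci are hard-assigned to the terminal node with
  the largest membership weight; fuzzy weights are retained internally.
  Classes are renumbered by increasing mean methylation; exact ties go to
  the larger class first.

## Omnibus max-|t| permutation test

Per class: simple least squares of aggregate methylation on the marker
(marker per 10 percentage points). The omnibus statistic is max_k |t_k|.
Null: the marker vector is shuffled across subjects — one shared shuffle
per replicate, since the maximum must be over jointly permuted fits — and
all regressions are recomputed; default B = 10,000. The p-value uses the
add-one estimator (1 + #{null ≥ observed})/(B + 1), which cannot return 0.
The 0.95 quantile of the permuted maxima is reported as a symmetric
per-class significance limit (the dashed lines in the plots). Constant
aggregate columns get t = 0 with a warning; a noiseless fit reports t at a
cap of 1e6. B < 100 is rejected as an unstable null. Covariate-adjusted
class regressions are intentionally not the default: the omnibus contrasts
exactly the two named variables.

## TFBS gene-set enrichment

Per-locus statistics are the t-values of simple β-on-marker regressions;
loci are ranked by descending t with ties kept in locus-id order. The
enrichment score is the signed extremum of the weighted KS running sum:
hits advance by |t|^p normalized over the set (p = 1 default; all-zero
statistics fall back to unweighted steps), misses retreat by 1/(N−m).
Significance by phenotype permutation (marker shuffled; the matrix — and
hence the locus correlation structure — untouched). NES divides ES by the
mean |null ES| of the same sign; p is the add-one same-sign tail; FDR q is
the ratio of null to observed NES tail fractions, computed separately by
sign and clipped to 1. Sets outside [5, 500] loci are dropped; B < 100 is
rejected.

## Preprocessing conventions

- β from intensities follows the printed platform formula exactly, with no
  normalization; negatives are clamped before the ratio, so β ∈ [0, 1).
- The outlier screen reduces each subject to (mean β, SD β, fraction
  β > 0.7) — a 3-dim summary keeps the covariance well conditioned — and
  flags squared Mahalanobis distances above the χ²(3) upper-α quantile,
  α = 0.001 by default. α ≥ 1 disables flagging. The feature space and
  threshold are package choices; the source describes only "a Mahalanobis
  screen".
- Autosomal filtering drops X/Y loci, preserves order, and is idempotent.
- Pyrosequencing stays on the 0–100 scale, array β on 0–1; every conversion
  is explicit (the per-10% rescaling happens inside the model fits).
- Growth boundaries are strict: percentile exactly 10 or 90 is AGA.
- Matching is greedy and deterministic: cases in id order, nearest eligible
  control by maternal-age gap, ties by gestational-age gap then lowest id.
  Unmatched cases are reported, not fatal.
- Model fits are complete-case; binary covariates with no variation in the
  realized sample (alcohol use, at prevalence 3/380, is occasionally all
  "no") are dropped with a warning rather than left to produce an aliased
  design.

## Problem sizes

Desk-scale defaults keep every check fast while preserving the structure:
2,000 loci stand in for the platform's 26,486 autosomal loci (full scale is
a config field), clustering checks use 2,000 × 100, permutation error-rate
studies use 500 replicates at B = 200, and enrichment power checks use a
few hundred loci with B = 500. The calibration experiments average 50
cohorts of n = 380, matching the reported sample size.

## Known limitations

- The beta-mixture M-step is guarded-MLE rather than a full multivariate
  maximizer; pathological columns fall back to method-of-moments.
- BIC split acceptance with 2S-parameters-per-component is conservative for
  very small nodes; classes with < ~30 loci at 100 subjects may fail to
  split even when truly distinct.
- The bioinformatic class census is data-driven (38 nonempty classes at the
  default frequencies and 2,000 loci); the number of observed attribute
  tuples grows with locus count.
- The permutation FDR for enrichment pools null NES across sets, which is
  slightly conservative when set sizes are very heterogeneous.
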