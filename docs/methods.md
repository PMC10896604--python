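# Methods

This note records the statistical model behind each pipeline stage, the
defaults and why, the numerical choices, and what the synthetic-cohort
experiments do and do not demonstrate.

## Study design and data model

The pipeline targets a two-arm case–control design: tumor tissue from
patients given preoperative radiotherapy, split into good (GR) and poor
(PR) responders by tumor regression grading, 12 patients per arm. Inputs
are wide feature tables (features × samples, non-negative abundances, NaN
= not detected) for a proteome layer (~2741 features) and a metabolome
layer (~119 features), plus per-sample clinical covariates.

Abundances are modeled as log-normal: MS intensity distributions are
right-skewed and multiplicative. All standardized effects, effect sizes
and tests therefore operate on the natural-log scale; fold changes are
reported on the original scale. Univariate inference uses observed values
only (no imputation); multivariate stages (PCA, HCA, SVM panels, QEA)
require complete data and use half-minimum imputation first — a deliberate
separation so that imputation artifacts cannot create univariate
significance.

## Normalization

* **TIC**: each sample is divided by its summed observed intensity and
  multiplied by the cohort **median** total. Rescaling to the median (vs.
  relative abundance summing to 1) keeps values on the original intensity
  scale; every downstream statistic used here is invariant to the choice.
* **log + autoscale**: natural log, then per-feature mean-centering and
  division by the sample SD (ddof = 1). Zeros are treated as non-detects
  before the log. Zero-variance features are dropped with a warning.

## Adaptive univariate test

Gates (both at α_gate = 0.05, configurable): Shapiro–Wilk per group for
normality; Levene with median centering (Brown–Forsythe) for
homoscedasticity — the robust default of common implementations. Routing:
both groups normal and homoscedastic → pooled *t*; normal but
heteroscedastic → Welch; otherwise Mann–Whitney (exact null distribution
when either group has n < 8 and the data are tie-free, tie-corrected
normal approximation otherwise). Degenerate input (all values identical)
returns p = 1. Features with fewer than 3 observed values in a group are
skipped and counted.

Effect sizes are paired to the test branch: Hedges' *g* (bias factor
J = 1 − 3/(4n − 9), pooled-SD denominator) with magnitude bands
medium ≥ 0.5 / high ≥ 0.8 for the *t*/Welch branch; rank-biserial
correlation (ties half-weighted) with bands medium ≥ 0.3 / high ≥ 0.5 for
the rank branch. Fold changes: classical mean ratio and the
Hodges–Lehmann-type median of all pairwise between-group ratios, both
oriented first-listed group (GR) over second.

Significance is recorded at **both** raw p < 0.05 and BH q < 0.05, and the
summary reports both counts: the two rules answer different questions
(per-feature error rate vs. false discovery rate across the layer) and
both thresholds are conventional in discovery omics.

Benjamini–Hochberg adjustment is the exact step-up formula
q₍ᵢ₎ = min₍ⱼ≥ᵢ₎ p₍ⱼ₎·m/j capped at 1, implemented in ~10 lines and
cross-checked in the tests against both brute-force enumeration and
statsmodels.

**Group-exclusive features.** A feature observed in ≥ min_detected samples
of one group (default: half the smaller group size) and zero samples of
the other is reported as exclusive to that group instead of being tested —
a detection statement, not a p-value.

**Clinical covariates.** Continuous covariates go through the same gated
test choice. Categorical 2×2 tables use Fisher's exact test (two-sided,
sum of table probabilities ≤ observed); r×2 tables with r > 2 use Pearson
chi-square without continuity correction. Fisher for 2×2 is a deliberate
choice: at n = 24 the exact test is the defensible default, and it exactly
reproduces all five published 2×2 p-values of the reference cohort
(1.0, 0.22, 1.0, 0.64, 0.67), which the uncorrected chi-square does not.

## Classification

* **Univariate AUC**: rank-based U statistic over all samples, reported
  after orientation max(AUC, 1 − AUC) with the favoured direction kept.
* **LOO logistic regression**: one feature + intercept, small fixed ridge
  (C = 10⁴) so complete separation stays defined, prediction threshold
  0.5, PR as positive class; scored by balanced accuracy (TPR + TNR)/2,
  which is invariant to class imbalance. Zero-variance features are scored
  at chance (0.5) and flagged: feeding them through LOO would return the
  intercept-only majority vote, which under LOO with balanced classes
  always opposes the held-out sample (balanced accuracy 0 — the
  anti-learning artifact), a property of the estimator, not of the
  feature. For the same reason the LOO permutation null for noise features
  lies **below** 0.5; the meaningful null guarantee, asserted in the
  tests, is the absence of optimistic bias.
* **MCCV/SVM panels**: defaults 100 iterations, train fraction 2/3 drawn
  per class (balanced subsampling), linear SVM with C = 1. Features are
  re-standardized inside each training split so the cohort-level scaling
  leaks nothing into the held-out samples. Ranking is single-shot by
  |weight| of an all-features fit — deterministic and cheap; recursive
  elimination is intentionally not the default. Held-out probabilities use
  a logistic link σ(d) on the signed decision value (an uncalibrated but
  monotone map — AUC and frequency ranks are unaffected by the lack of
  calibration). Per panel size: per-sample probabilities averaged across
  iterations, AUC of those averages, a 95% band from the 2.5/97.5
  percentiles of per-iteration held-out AUCs, balanced accuracy at
  threshold 0.5, and per-feature selection frequency. The reporting panel
  is the size with maximal AUC, ties toward the smaller panel.

## Chemometrics

PCA by SVD of the centered samples × features matrix, with a fixed sign
convention (largest-magnitude loading element positive) for cross-run
determinism. HCA defaults to Ward linkage on Euclidean distances (both
configurable); the 2-cluster cut provides an agreement score against the
GR/PR labels; dendrograms serialize to Newick. Supervised clustering "on
the differential features" is the same operation after a feature filter.

## Enrichment

* **ORA**: one-sided hypergeometric upper tail P(X ≥ k), pathway members
  intersected with the measured universe first; expected hits
  = |hits|·m/|universe|; enrichment ratio = observed/expected.
* **QEA**: globaltest-style score — per standardized feature
  z = [Σᵢ(yᵢ−ȳ)xᵢ]², pathway statistic Q = mean over measured members —
  calibrated by label permutation (default 1000) with one permutation
  stream shared across pathways, so pathway p-values are mutually
  comparable; add-one smoothing gives p ≥ 1/(B+1). Permutation rather than
  the asymptotic distribution: assumption-free and cheap at n = 24.
* **Joint pathway analysis**: protein and metabolite hits and universes
  pooled (namespaced identifiers) into a single ORA. "Pathway impact" is
  defined here as the enrichment ratio; topology-weighted impact requires
  graph structure GMT files do not carry, so an optional node-weight hook
  computes a weighted hit fraction when centralities are supplied.

BH adjustment is applied once per method run, across pathways.

## Correlations

Pearson r on pairwise-complete observations (min 3 pairs), p from the
t transform with n − 2 df, BH across the reported pair list; the screen
keeps |r| > 0.8 with p < 0.05 (both configurable) and the full matrix is
always written too. The dose analysis correlates selected biomarkers with
delivered radiation dose on all samples and within each response group
separately: a feature that merely tracks group membership shows a strong
overall dose correlation (the groups received different dose schemes) that
vanishes within groups, and the stratified view exposes exactly this.

## Synthetic cohort generator

What it emulates: 12 + 12 samples; per-feature log-normal baselines with
location ~ N(12, 2) and log-scale SD ~ U(0.3, 0.7) (typical of TIC-scaled
MS intensities); planted differential features shifted by
effect_size × (that feature's log-SD), i.e. calibrated in Hedges'-g units;
a fraction of features with centered-exponential (right-skewed) log-scale
noise that deterministically routes to the rank branch; group-exclusive
features missing in every sample of the non-owning group;
missing-at-random dropout applied before TIC normalization; a
Table-1-like clinical covariate table whose group association is
controlled by a single strength parameter (0 = independent). A root seed
derives fixed-offset child streams per layer, so resizing one layer never
reshuffles another.

Defaults: frac_differential = 0.2, effect_size = 2.0, frac_nonnormal =
0.2, frac_exclusive = 0.01 (≈ the ~20/2741 exclusives typical of such
cohorts), missing_rate = 0.05.

What it does **not** emulate: intensity-dependent (left-censored)
missingness, feature–feature correlation structure, batch effects,
peptide-to-protein roll-up noise, or identification error. Passing the
planted-recovery experiments therefore demonstrates the statistical
machinery is correct and calibrated under the assumed model — not that
real tumor cohorts will yield comparable power. The MAR missingness model
in particular is an assumption; real MS non-detection is abundance-
dependent.

## Experiment scales

The self-validation experiments use: type-I calibration — 50 null cohorts
× 200 proteome features; planted power — 20 cohorts × 250 features at
g = 2; MCCV recovery — 20 cohorts of 10 planted (g = 3) among 500 null
features, 100 MCCV iterations; QEA — 50 null cohorts (500 permutations)
and 20 planted cohorts (1000 permutations); plus one full-scale end-to-end
run (24 × (2741 + 119), all stages). These sizes give stable estimates
(binomial SE < 1.5% on each rate) while keeping the whole suite
desk-scale.

## Known limitations

* The adaptive test gates and then tests on the same data; the resulting
  type-I rate is nevertheless calibrated (measured 0.03–0.07 across null
  cohorts), since each branch is valid under the null it is routed to.
* FDR control is per omics layer, not global across layers.
* MCCV selection frequency is a stability, not an inferential, ranking;
  no significance is attached to frequency differences.
* QEA treats pathway members as exchangeable (no topology weighting
  unless node weights are supplied).
* The SVM probability link is uncalibrated; per-sample averaged
  probabilities are comparative scores, not risk estimates.
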