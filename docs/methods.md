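# Methods

This note documents the models, defaults and numerical choices behind
`parcelmark`, and what the synthetic cohorts do and do not establish.

## Synthetic cohort model

The generator emulates a case/control neuroimaging cohort described by
parcellated phenotypes. Its defaults mirror the reference study design:
102 cases acquired at one local site (batch 1) and four control batches
of 25 + 25 + 300 + 300 subjects (two small local batches, two large
external repositories), 360 cortical parcels, 34 subcortical/other
structures.

**Structural measures.** Population mean templates per parcel are fixed
(independent of the cohort seed): surface area is log-normal around
480 mm² per parcel, thickness ≈ N(2.6, 0.2) mm, myelin ratio
≈ N(1.5, 0.15), subcortical volumes log-normal around 3,000 mm³, and
eTIV 1.5 × 10⁶ mm³. Subject values are Gaussian around these templates
with residual SDs of 10% (area), 0.12 mm (thickness), 0.10 (myelin),
12% (subcortical) and 1.3 × 10⁵ mm³ (eTIV) — magnitudes typical of
adult parcellated data. Everything is Gaussian by design: the pipeline
under test consists of t-statistics, correlations and rank-based AUCs
whose *calibration* is the test surface; distributional realism is not.

**Planted effects.** `effect_map` adds `d · SD` to the case mean on the
listed parcels, so a two-sample Cohen's *d* computed on the generated
data recovers the planted value (the parameter-recovery oracle).
`etiv_effect_d` shifts intracranial volume only — total surface area is
the independent sum of parcel areas — so a negative shift yields the
"smaller head, unscaled cortex" pattern in which area-per-volume rises
in cases. Optionally, each case's planted shift scales with its number
of reported trait types (`effect_scales_with_types`), which ties
classifiability to the number of types.

**Thickness coupling.** Thickness follows a one-factor model
`x = μ + σ(√ρ·f + √(1−ρ)·ε)` with a per-subject latent factor *f*; the
across-subject inter-parcel correlation is exactly ρ (0.30 in controls,
0.30 + `coupling_boost` in cases). This is the generative counterpart
of raised structural covariance, recoverable by the
`structural_covariance` estimator.

**Functional connectomes.** A control template correlation matrix has a
5-block community structure (within-block 0.30, between 0.05) with 10%
hub parcels (every 10th parcel) whose edges are doubled and capped at
0.8; the matrix is eigenvalue-floored and renormalized to a valid
correlation matrix. Case templates shrink every off-diagonal entry
toward the mean edge weight by `hub_flattening` ∈ [0, 1], removing the
hub/spoke asymmetry. Per-subject time series are the template's
Cholesky factor applied to white noise plus observation noise
(SD 0.5). The generator guarantees T ≥ p/4 timepoints (default 300).
There is deliberately no BOLD autocorrelation, motion structure or
hemodynamics: conclusions about those aspects of real data cannot be
drawn from these tests.

**Batch effects** are applied last, per measure and batch, as
`x → μ + scale·(x − μ) + shift·σ` — exactly the location/scale family
the harmonization model assumes. Shifts are expressed in residual-SD
units, scales multiply the residual.

**Demographics.** Ages are uniform 18–65 and sex is Bernoulli
(75% female by default); these exist so harmonization has covariates —
their realism is irrelevant to what is being tested. Cases' number of
trait types is zipf-like over 1–8 (exponent 1.2: many 1-type, few 5+).

## Harmonization

`combat_fit` implements parametric empirical-Bayes location/scale
adjustment: feature-wise standardization after regressing out
covariates and batch means (pooled residual variance, weighted grand
intercept), per-batch moment estimates of additive/multiplicative
effects, Normal (additive) and Inverse-Gamma (multiplicative) priors
estimated across features by the method of moments, and the standard
iterative fixed-point posterior update (tolerance 1e-6, ≤500
iterations). Output on a reference fixture matches R `sva::ComBat`
to ~1e-5.

Notes on behavior that tests rely on:

* EB shrinkage leaves small residual per-feature batch differences (the
  posterior is pulled toward the across-feature prior mean); this is
  canonical, not a defect, and `sva` leaves identical residuals.
* With a single batch the adjustment is the identity (there is no
  between-batch variation to model); canonical EB would still rescale
  by the prior mean n/(n−1), which is undesirable here.
* Whether group status enters the design is a flag: including it
  protects group differences from absorption into batch terms; omitting
  it emulates harmonizing against unlabeled reference data.
* Only raw measures (area, thickness, myelin, subcortical volumes,
  eTIV, partial-correlation edges) are harmonized; derived biomarkers
  are computed from harmonized inputs and never re-harmonized.
* eTIV-normalized quantities divide harmonized volumes by harmonized
  eTIV (harmonize first, normalize second).

## Feature sets

Thirteen biomarkers (see `BIOMARKER_REGISTRY`). Pairwise feature sets
use the fixed upper-triangle (i < j, row-major) ordering, length
n(n−1)/2 = 64,620 for 360 parcels. They are PCA-reduced to the smallest
component count reaching 95% of training variance (capped at
n_train − 1), with the reducer fitted on training folds only and
applied to held-out folds — fitting it on all subjects would leak
held-out information into the features. Surface-area parcels enter
unweighted (vertex-level thickness weighting would require vertex data,
which is out of scope); parcel-level thickness is taken as given (a
vertex-median would apply upstream of this package).

## Connectome derivations

Partial correlations come from the inverse of a shrinkage-regularized
correlation matrix, `R_λ = (1−λ)R + λI`,
`pr_ij = −Ω_ij/√(Ω_ii Ω_jj)`. With 360 parcels and a few hundred
timepoints the unregularized inverse is ill-posed; `λ="auto"` uses the
analytic optimal intensity (Schäfer–Strimmer: summed sampling variances
of the off-diagonal correlations over their summed squares). The p=2
identity (partial = Pearson as λ→0) and chain-graph conditional
independence pin correctness. Degree centrality is the per-region sum
of absolute partial correlations.

Gradients are computed from Pearson (not partial) connectomes: PCA over
the 360 rows (each region's connectivity profile), first two
components. Per-subject PCA axes carry sign/rotation indeterminacy, so
subject scores are aligned to a control-group-mean reference by
orthogonal Procrustes over the two components. Scores are zero-mean and
orthogonal in the fitting space (alignment rotates them jointly). No
thresholding or sparsification is applied before the PCA — that would
add a free parameter with no principled default.

## Classification protocol

Stratified k-fold (default 5) with, per training fold: majority-class
down-sampling to the minority count (seeded), fold-internal PCA for
wide feature sets, optional inner 3-fold selection of the
features-per-tree parameter over a grid, then a 500-tree random forest
(scikit-learn) with per-tree feature subsampling. Held-out vote shares
(fraction of trees voting "case") are pooled across folds; AUC is the
Mann–Whitney rank statistic with half credit for ties (stated
explicitly for bit-reproducibility); sensitivity/specificity use the
0.5 vote threshold. Constant feature columns are dropped with a log
entry. Down-sampling touches training folds only, so held-out class
frequencies are untouched.

Permutation nulls re-run the full protocol on shuffled labels
(≥100 shuffles for CI reporting); significance is the upper-tail
proportion with +1 correction.

The default mode evaluates all subjects in one k-fold pass. The staged
mode splits cases 25/25/remainder into discovery/demonstration/
generalization by number of trait types (3+ for the first two stages,
seeded tie-break), halves external-batch controls between discovery and
demonstration, and sends local controls to discovery. The
features-per-tree parameter is tuned on discovery and frozen for the
later stages. The generalization stage holds cases only, so they are
evaluated against the demonstration controls. With fewer than 50
multi-type cases the stage quotas shrink proportionally (warned and
recorded in the plan's rule trace).

## Statistics

Pooled-variance (Student) t-tests per region — matching the pooled-SD
Cohen's *d* — with a Welch switch available; Benjamini–Hochberg
step-up FDR (statsmodels). AUC↔d conversion under the binormal
equal-variance model: `d = √2·Φ⁻¹(AUC)`. Mahalanobis
`D = √((m_A−m_B)' S⁻¹ (m_A−m_B))` with pooled covariance; the
small-sample correction is the standard unbiased estimator
`D_u² = ((N−p−3)/(N−2))·D² − pN/(n_A n_B)`, floored at zero in the
public API (the unfloored value is used internally when assessing the
correction itself, since its null mean is zero only without the floor).
`detectable_d` inverts the noncentral-t power function by bisection
(tolerance 1e-6), with a guard for scipy's noncentral-t underflow deep
in the power ≈ 1 regime.

## Problem sizes in the test and acceptance runs

The statistical checks run on cohorts the pipeline's asymptotics are
already visible at: permutation calibration on 200 subjects × 360
features with 200 shuffles; parameter recovery at 150 per group;
harmonization checks at 100–200 per batch; hub-flattening at 100 per
group with 300 timepoints; the Mahalanobis-correction simulation at
p=35, n=128/109 with 500 replicates. Scaled-down variants of the same
checks (smaller parcel counts, 50–150-tree forests) cover the remaining
protocol properties.

## Known limitations

* The generator's Gaussian, temporally-white time series cannot speak
  to autocorrelation-induced bias in connectivity estimates.
* Batch scale effects multiply residuals about the *population*
  template mean; for parcels carrying a planted group shift the shift
  is scaled too — a second-order deviation from the strict ComBat
  family, negligible at the effect sizes used.
* PCA reduction uses a variance target, not a component-count grid; the
  95% default is a convention, exposed as a parameter.
* The exact regularization used by published partial-correlation
  connectomes varies; the shrinkage estimator here is a standard,
  well-conditioned choice, pinned by oracle identities rather than by
  replication of any specific recipe.
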