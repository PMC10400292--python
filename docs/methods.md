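# Methods

`radgen` implements a generalization-optimized CT-radiomics pipeline and the
synthetic multi-site cohorts needed to exercise it end to end. This note
documents the models, the defaults and why they were chosen, what the
synthetic data does and does not emulate, and the numerically delicate
choices.

## Problem setting

A radiomic signature fit at a handful of hospitals routinely fails at the
next one: reconstruction kernel, slice thickness, pixel spacing and vendor
calibration all leave fingerprints on quantitative image features that can
exceed the biological signal. The pipeline here combines image-space
harmonization with a hyperparameter search that optimizes *cross-center
stability* rather than raw cross-validated performance, and judges external
validity by whether the validation-center AUC falls inside the bootstrap 95%
confidence interval of the discovery (out-of-fold) AUC.

## Synthetic cohorts

No patient data is distributed or required; two generators provide the study
material.

**Voxel fidelity.** Each patient is an analytic thorax phantom: an
ellipsoidal soft-tissue body (semi-axes 66 x 52 x 62 mm by default), two
mirror-symmetric ellipsoidal lungs, and a spherical nodule with a soft edge
and an intra-lesional Gaussian random texture field (sd 40 HU, 2.5 mm
correlation length). The texture matters: with internally homogeneous
nodules, fine-scale filter channels contain only scanner noise, and texture
features would measure the protocol rather than the lesion. An acquisition
simulator then produces each site's scan: slice thickness as a boxcar
average over contiguous thin slices followed by decimation (detector
integration; chosen over a Gaussian z-blur because averaging has an exact
constant-volume identity case), in-plane resampling to the site's pixel
spacing, the reconstruction kernel as a single unsharp-mask strength (<1
smooths, >1 sharpens), i.i.d. Gaussian HU noise, and an additive vendor
calibration bias. The four default site profiles span 0.7-1.1 mm pixels,
2-4 mm slices, kernel strengths 0.85-1.3 and biases of -30 to +40 HU, with
similar noise floors (8-11 HU) — vendors differ far more in geometry,
kernel and calibration than in noise.

The binary endpoint (six-month progression-free survival, PFS-6) follows a
logistic model on true nodule radius and density with configurable
coefficients; the coefficients are study parameters, not estimates.

**Tabular fidelity.** For experiments needing hundreds of patients, a
feature-table generator draws latent standard-normal "radiomic" features; a
sparse subset carries a standardized class separation (`effect_size`), and
per-(site, feature) batch effects apply as `x <- x*(1+scale) + shift`.
Five clinical covariates (lesion radius, ECOG, age, smoking, first-line
immunotherapy) are generated with a mild outcome link and no batch effects.
Three design elements reproduce the multi-center failure mode:

* discovery sites' batch-effect vectors share a common component
  (correlation 0.995 in the study scenario) while the validation site's are
  independent and doubled in magnitude — three same-network academic
  centers versus an external fourth;
* the validation site loses half the imaging effect size in the raw view
  (thick slices genuinely attenuate fine-texture contrast);
* a `batch_attenuation` knob scales all protocol effects *after* every
  random draw, so the same seed yields exactly paired "raw" and
  "post-harmonization" cohorts (harmonized residual 0.15 — image-space
  harmonization is good but imperfect; kernel effects in particular
  survive).

Purely additive per-feature site shifts cannot degrade within-site AUC of a
linear scorer (AUC is rank-invariant to per-feature offsets); the
multiplicative gain mismatch and validation signal loss are what make naive
transfer fail, and both are physically motivated.

Clinical covariate tables are sampled independently per patient from
site-specific marginals (only marginals are published for the emulated
642-patient cohort; no copula is imposed). ECOG marginals are normalized
over the 497 reported; PD-L1 missingness (75/512) is kept explicit.

**What passing tests do not show.** The phantoms have no airways, vessels,
mediastinum or pleural effusions; acquisition is a separable linear model
plus noise, not filtered backprojection; the tabular batch model is affine.
Success here demonstrates the machinery — that the pipeline removes exactly
the variation the simulator injects and that the search's stability rule
behaves as designed — not clinical performance on real scans.

## Harmonization

Fixed stage order: resample to 1 mm isotropic voxels (trilinear; output
shape per axis `floor(n*s/target + 0.5)`, preserving physical extent) →
truncate HU to [-400, 1024] → Laplacian-of-Gaussian filtering at physical
scales sigma ∈ {1, 3} mm. Truncation precedes filtering so supra-range
artifacts cannot leak into the filtered channels, and trilinear (order-1)
interpolation cannot overshoot the truncation range. The LoG is separable:
per axis, a sampled Gaussian (normalized to sum 1) and its second
derivative, with the derivative kernel projected to exactly zero DC gain so
a constant volume maps to exactly zero; boundaries replicate. The kernel
radius is 4 sigma. The filter scale list is configuration: {1, 3} mm is the
default reading of the two-scale setup, and sigma^2 ∈ {1, 3}
(sigma ∈ {1, √3}) is reachable by config for anyone preferring that
parameterization.

## ROI determination

Three stages, all thresholds configuration-exposed:

1. **Alignment + chest isolation.** Principal axes of the body voxel cloud
   (> -200 HU) are rotated onto the grid axes (largest variance to the
   cranio-caudal axis), each Euler angle clamped to ±15°. Chest mask:
   threshold, 3-mm opening, largest 26-connected component, 5-mm closing,
   hole filling.
2. **Lung segmentation.** Air-like voxels (≤ -400 HU — inclusive because
   truncation clamps parenchyma exactly to the bound) inside the chest,
   border-connected components discarded, ≥5 cm³ per component and ≥50 cm³
   total, at most two components kept. Refinement closes each component
   with a 3-mm ball and fills holes per component — per component so the
   two lungs can never bridge across the mediastinum, with hole filling
   re-including dense nodules embedded in parenchyma.
3. **Nodule delineation.** Otsu clustering of intensities in a 40-mm box
   around the annotation midpoint, restricted to the lungs plus a 5-mm
   pleural dilation; dense components whose mirror image across the
   mid-sagittal plane is also dense are suppressed as symmetric anatomy
   (the annotated component is always retained); the component containing
   (else nearest within 20 mm to) the midpoint becomes the ROI, bounding
   box padded two voxels. Lesion radius is half the annotation length.
   Lesions with no dense component near the midpoint raise a countable
   `UndelineatableLesion` — the analogue of excluding patients whose
   lesions cannot be delineated, an explicit outcome rather than a crash.

Otsu was chosen over k-means because it is deterministic and
parameter-free; the mid-sagittal mirror plane implements the lungs'
left/right symmetry with minimal machinery.

## Feature signature

Exactly 94 features by default: 19 first-order statistics on the
resampled+truncated channel and 75 texture features on the sigma = 1 mm LoG
channel — GLCM 24, GLRLM 16, GLSZM 16, GLDM 14, NGTDM 5. Definitions follow
the IBSI reference formulas; moments are population-normalized.
Discretization is fixed bin width (default 25 for both channels), which is
min-referenced and therefore shift-invariant. Texture neighborhoods are
3-D, 26-connected; GLCM and GLRLM merge counts over the 13 unique
direction offsets before feature computation (co-occurrences symmetrized),
and gray-level terms use the actual discretized level values. Shape
features are omitted deliberately and wavelet-band features, when enabled,
are always flagged `excluded_by_default` — both families track acquisition
parameters more than biology. Computing the 75 texture features on a single
LoG channel is forced by arithmetic (19 + 75 = 94 rules out per-scale
duplication); sigma = 1 mm is the declared default and per-channel
extraction sits behind a flag. Every matrix builder is validated against a
naive enumeration oracle in the test suite.

## Selection and models

* **Correlation pruning:** greedy scan in column order; a feature is
  dropped iff |Spearman rho| ≥ threshold (threshold ∈ [0.8, 1]) with an
  already-kept feature. Constant features get rho = 0 with a warning.
* **Ranking:** one-way-ANOVA F-test, or neighbor-margin weights
  (ReliefF with 10 nearest hits/misses; SURF with the global mean-distance
  threshold; MultiSURF with per-instance mean − sd/2 thresholds), computed
  on range-normalized features over all instances — deterministic.
* **mRMR:** greedy forward selection maximizing relevance minus mean
  absolute Pearson correlation with the selected set. Relevance is the F
  statistic mapped onto the correlation scale via the exact two-class
  identity r² = F/(F + n − 2): a raw F (often in the hundreds) would
  drown the |r| ≤ 1 redundancy term and an exact duplicate of a selected
  feature could win. The mapping is monotone in F, so k = 1 reduces to the
  F-test top-1.
* **Models:** L2 logistic regression (inverse penalty C, log-uniform
  1e-3..1e2) and gradient-boosted trees (25-150 trees, depth 1-4, learning
  rate 0.01-0.3 log-uniform, subsample 0.5-1). Standardization statistics
  come from the training fold only — the look-ahead bias this protocol is
  designed to avoid.
* **Metrics:** AUC (Mann-Whitney, ties half credit), Brier score,
  Nagelkerke R² against the prevalence-only null, Youden's J maximized
  over thresholds.

Five clinical features (lesion radius, ECOG, age, smoking, first-line ICI)
are fixed: they bypass pruning and ranking and are always in the model; the
total feature budget k ∈ [5, 20] includes them.

## The search

A scrambled Sobol sequence (seeded Owen-type scrambling; scrambling avoids
the unscrambled sequence's degenerate first point) covers the 9-dimensional
joint space of pruning threshold, ranking method, k, model family and model
hyperparameters. Every trial is scored by leave-one-center-out
cross-validation. Per-fold selection statistics (Spearman and Pearson
matrices, F scores, relief weights) depend only on the fold's training
data, so they are cached per fold and reused across trials; relief weights
are computed once on the full feature set and restricted to the pruned
survivors rather than recomputed per threshold. mRMR is re-run per trial
from the cached matrices since its redundancy term depends on the survivor
set.

**Final-model rule.** Candidates are trials within one fold standard error
of the best mean AUC *and* within tolerance of the best Brier (0.02) and
Nagelkerke R² (0.05) — agreement of discrimination, calibration and fit
across folds as the stability proxy. The winner has the smallest
across-fold AUC spread (ties: fewer features, then trial id). If the
agreement filter empties the candidate set, a logged (mean, −sd)
lexicographic fallback applies. The winner is refit on the full discovery
cohort using the *consensus* (majority vote) feature set of its fold-level
selections, padded from a full-discovery re-selection if short: re-running
selection from scratch on all discovery data can produce a materially
better model than the fold models the confidence interval describes, which
systematically pushes the validation AUC above the interval.

**Generalizability verdict.** The discovery AUC is the winner's
leave-one-center-out out-of-fold AUC (out-of-fold rather than refit
predictions — the honest estimate of cross-center transfer); its 95% CI is
a percentile bootstrap (default 2000 replicates) resampling patients with
replacement stratified by outcome. The validation-center AUC is computed
once, after the model artifact is frozen — enforced by an audit trail that
raises if validation data is touched first — and the verdict is pass iff
it falls inside the closed interval.

**Non-inferiority.** An exploratory paired permutation test on the AUC
difference of two models over the same patients: the null swaps the two
models' predictions per patient with probability 1/2;
p = (1 + #{|Δ*| ≥ |Δ|}) / (n_perm + 1), two-sided, with the mean null
difference reported.

## Diagnostics

Principal-coordinate embedding is classical metric scaling of Euclidean
distances on standardized features — algebraically identical to PCA scores
in that metric, so the choice between the two labels is moot; component
signs are fixed by the largest-loading-positive convention. Batch structure
is quantified as the mean silhouette of a grouping variable (site, vendor,
kernel, slice thickness) on standardized features; silhouette is the
quantitative surrogate for "visible clustering" in an ordination plot.
Cohort baseline tables are compared with the chi-square family — Yates
continuity correction for 2×2 tables, none for r×c, Fisher's exact (with a
flag) when a 2×2 expected cell is below 5 — and t or Mann-Whitney tests for
continuous variables after a Shapiro normality screen. These conventions
reproduce the emulated cohort's published baseline p-values (sex 0.653,
histology 0.034, PD-L1 0.222) from the printed counts.

## Problem sizes in the test suite

Simulations are scaled to desk hardware as the package's own test design:
the generalizability contrast runs 10 seeds × 2 arms × 32 Sobol trials on
a 512-patient discovery / 600-patient validation table; ROI recovery uses
20 phantoms at 1.5-2 mm source spacing; the voxel-path silhouette
comparison uses 10 replicates of two five-patient sites on compact
phantoms. The validation arm of the tabular scenario is larger than the
emulated cohort's 130 patients so that verdicts reflect the model rather
than validation sampling noise.

## Known limitations

* The acquisition simulator has no beam hardening, scatter, or
  reconstruction-specific noise correlation; kernel effects are a single
  scalar.
* The alignment stage assumes scans are roughly axis-aligned (±15°).
* Relief weights are computed on the full feature set per fold, not per
  pruning threshold (a deliberate efficiency trade documented above).
* The bootstrap CI ignores fold-level model refitting (predictions are
  frozen out-of-fold values), and the discovery estimate carries the
  winner's selection optimism; both are properties of the protocol being
  implemented, not bugs to fix here.
* Single-voxel ROIs return NaN for dispersion statistics rather than a
  value; the delineation stage never produces them in practice.
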