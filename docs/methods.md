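# Methods

## Imaging model and conventions

All volumes live on regular axis-aligned grids with voxel centers at
`origin + index · spacing` (millimeters). A DCE visit is a pre-contrast
volume I(t0) and two post-contrast volumes I(t1), I(t2); default times are
0, 2.5 and 7.5 minutes after contrast injection, matching the acquisition
protocol of the trial population this pipeline targets. The inter-visit
transform is stored as a displacement field u on the pre-treatment (fixed)
grid with T(x) = x + u(x) mapping into the early-treatment image; all
derivatives are taken spacing-aware in world units. Sampling outside a
grid's extent clamps to the nearest edge value.

## Deformation features

The local deformation at a voxel is summarized by the principal stretches
λ1 ≥ λ2 ≥ λ3, taken as the **singular values** of ∇T (computed by central
differences at interior voxels, one-sided on boundary faces, which are
flagged). Singular values rather than raw eigenvalues of ∇T(∇T)ᵀ are used
because the Jacobian identity J = λ1λ2λ3 = det ∇T must give the local
volume ratio; the eigenvalues of ∇T(∇T)ᵀ multiply to det(∇T)², which would
square it. An `eigenvalues` mode is kept behind `stretch_mode` for
comparison. Degenerate cases follow fixed conventions: ADI clamps λ2, λ3
below at 1e-8 before division (clamped voxels flagged but kept in the map
support so downstream denominators are stable); SRI takes the limiting
value 1 when λ2 = λ3 with λ1 > λ2 (rod limit) and 0 with an `isotropic`
flag when all three stretches tie. Strict orderings are relaxed to ≥ —
ties are common in synthetic fields.

## Kinetic features and PRMs

PE is the maximum relative enhancement over the two post-contrast times,
with t_PE the earlier time on ties (only two post-contrast frames exist in
this protocol, so the argmax set is {t1, t2}). WIS = PE/(t_PE − t0) is
granted when a positive enhancement peak exists; the printed alternative
condition (t_PE ≠ 0 minutes), vacuous under this timing, is available as
`wis_condition="literal"`. WOS uses the (t2 − t_PE) denominator with a zero
branch when t2 = t_PE, exactly as the index is usually written; because
that mixed use of t_PE is internally odd, a `(t2 − t1)` denominator variant
is exposed (`wos_denominator="t2_minus_t1"`). SER = (I(t2) − I(t0)) /
(I(t1) − I(t0)) is guarded to 0 (voxel flagged) when the wash-in difference
is under 1e-3 of baseline, since no guard is part of the standard
definition. Voxels with nonpositive baseline are flagged with zero
features.

Functional tumor volumes are segmented by thresholding PE and SER inside a
region of interest and keeping the largest 26-connected component. The
default thresholds (pe_min = 0.7, SER ∈ (0, ∞)) are configurable
placeholders: the published operational SER segmentation protocol is not
reproduced here.

PRM(x) = J(x) · F_early(T(x)) − F_pre(x) with F_early linearly
interpolated (nearest-neighbor sampling was a plausible alternative;
linear was chosen because every other resampling step in the pipeline is
linear). Support is FTV1; voxels mapped outside the early image are
flagged and excluded from summaries.

## Per-tumor indices

Fraction-increased uses a strict inequality with threshold 0 for PRM maps
and 1 for the Jacobian — "increased" for a volume ratio means expansion;
a literal J > 0 rule would always return 1. No dead-band is applied to the
PRMs (`prm_deadband` defaults to 0), since the index is defined on the
sign of the change. The entropy index bins the map into 32 equal-width
bins over the per-tumor observed range (the "number of levels" is only
well-defined for discrete data; 32 bins resolves the anisotropy maps
without emptying most bins at typical tumor sizes) and returns
Σ P log₂ P in the default `as_printed` convention — a nonpositive number,
minimized by a uniform histogram and 0 at a point mass. The conventional
negated Shannon form is available; downstream modeling is invariant to the
global sign flip up to coefficient sign.

## Preprocessing

Bias correction is a simplified iterative scheme with the same contract as
nonparametric non-uniformity correction: repeatedly estimate the residual
low-frequency log-intensity field by Gaussian smoothing at the requested
physical scale (mean-centered over the mask, so overall brightness is not
attributed to bias), accumulate, stop when the update drops below 1e-4 or
after 20 iterations. The corrected volume preserves the mask-mean
intensity exactly; the returned multiplicative field is strictly positive
with mask mean equal to 1 up to the same scalar (the two normalizations
cannot both be exact simultaneously, and preserving the image mean is the
property downstream stages rely on). Histogram matching is a monotone
piecewise-linear quantile map (constant images map to the reference
median); it is applied to the registration input only — matching the
volumes used for kinetic features would erase the longitudinal enhancement
change that the pipeline exists to measure. Resampling keeps the input
origin and physical extent, with linear or nearest interpolation.

## Registration

The cost is the saliency-weighted attribute dissimilarity
E = Σ ms(x, T(x)) · (1/d) · ‖A1(x) − A2(T(x))‖² · voxel_volume (d = 3),
plus a diffusion regularizer α‖∇u‖². Attributes are multi-scale smoothed
intensity, gradient magnitude and Laplacian (default scales 1 and 2 mm),
standardized over the mask. Mutual saliency compares the mean attribute
similarity (1/(1 + ‖Δa‖²/d_a)) in a core neighborhood around T(x) (center
plus 6 face neighbors at 1 voxel) against a surrounding ring (the 6 axis
directions at radii 2, 3, 4 voxels): weight = s_core/(s_core + s_ring + ε),
ε = 1e-6, so distinctive matches approach 1, ambiguous texture gives ≈ 0.5,
and points mapped outside the moving image get 0. The ring is sampled on
axis directions rather than a full shell to keep the computation a small
fixed number of interpolation passes.

`register_baseline` is a deliberately simple desk-scale solver — plain
gradient descent on the cost above with backtracking step control, three
resolution levels coarse-to-fine, saliency weights recomputed once per
level and treated as constants in the gradient. It exposes the same
interface and diagnostics a production attribute-matching registration
would: convergence flag, initial/final cost, and the fraction of mask
voxels with positive discrete Jacobian (flagged below 99%). Defaults:
α = 0.1, 100 iterations per level, initial step 0.4 voxels. On 48³
textured phantoms it recovers a 2-voxel translation to ≈ 0.4 voxel mean
endpoint error and a 4 mm Gaussian-bump deformation to ≈ 0.15 voxel in the
interior, in under a minute each. Since the result object carries the
warning flags the error contract requires, the function returns a
`RegistrationResult` holding the `DisplacementField` rather than the bare
field.

## Phantom generator

The phantom is an ellipsoidal tumor with a smooth sigmoid boundary
(default width 1.5 mm — crisp edges make interpolation-error tests noisy)
in a uniform background, each tissue class following a three-point
enhancement curve; baseline (t0) intensities of tumor and background are
equal, which makes blended-voxel kinetic features linear in tumor fraction
and the analytic kinetic-delta truth exact. The inter-visit deformation is
an affine map about the tumor center composed with Gaussian-bump
perturbations, specified forward (pre → early) to match the pipeline's
transform direction; the generator verifies the analytic Jacobian is
strictly positive at every grid voxel and rejects folding specs. Early
volumes are synthesized by evaluating the analytic tissue model at the
fixed-point inverse of each voxel (tolerance 1e-3 voxel, 50 iterations),
then degraded by a smooth multiplicative bias field (Gaussian-filtered
seeded noise, exponentiated, unit mean; default amplitude ±10%) and
additive Gaussian noise (default sd 1 on a baseline intensity of 100).
Everything is a deterministic function of the phantom specification and its
seed.

What the phantom does **not** emulate: MR physics (coil profiles, k-space
artifacts, partial-volume beyond linear blending), multi-site scanner
variation, and anatomically realistic breast structure. Passing tests
therefore demonstrate correctness of the computations and recoverability
under controlled degradation, not clinical performance on trial data.

## Cohort simulator

Per-patient covariates follow the target trial population: age
N(47.87, 8.9²) years, race binary (white-or-Hispanic, prevalence 74.2%),
hormone-receptor status 3-level with probabilities 38.6/37.1/24.3%
(coded 1 = HR+/HER2−, 2 = HER2+, 3 = triple-negative), log-normal
functional tumor volumes. Default n = 132. Imaging features default to
independent standard normals (a full phantom run per patient is supported
through the feature_generator hook but is not the default — the modeling
protocol's properties do not depend on how the features arose). pCR is
Bernoulli with logit = logit(baseline rate 0.30) + Σβz; RFS is exponential
with hazard 0.12/year · exp(Σγz), right-censored by an independent
Uniform(0, H) administrative time with H solved numerically so the
expected censored fraction matches `censor_rate` (default 0.705, matching
the 39-event / 93-censor mix of the reference population).

## Outcome modeling protocol

Continuous covariates are z-scored on the analyzed rows before fitting, so
reported odds/hazard ratios are per standardized unit; race and the
ordinal hormone score enter unscaled (a two-dummy categorical hormone mode
exists). Logistic fits use maximum likelihood (statsmodels), Cox fits the
partial likelihood (lifelines); separation or non-convergence yields a
flagged result with infinite AIC instead of an exception. AUC uses the
Mann–Whitney rank formulation with ties at 0.5; Harrell's C counts pairs
whose shorter observed time is an event, score ties at 0.5.

Cross-validation uses stratified folds (by pCR or by the event indicator),
built by a seeded shuffle-and-deal; a Cox fold draw leaving any training
or test fold without events is redrawn (logged). Within each fold,
candidates are ranked by the apparent (resubstitution) performance of
baseline+candidate on the training rows — no inner CV, matching the
protocol as described — with ties broken by lower training AIC, then
alphabetically. The nested sequence baseline + top-j candidates is fit for
j = 1..m, the training-AIC minimizer chosen and scored on the held-out
fold; the cross-validated metric is the unweighted mean of the per-fold
test metrics (per-fold averaging, not pooled scores). Consensus =
features selected in ≥ 80% of folds (4 of 5); the consensus model and the
baseline are refit on the full table and compared by the chi-square
likelihood-ratio test with df = number of added features; an empty
consensus returns p = 1. Rows missing pCR are excluded from pCR analyses
only.

Risk stratification dichotomizes the Cox linear predictor at the cohort
median (ties to low risk), compares the groups by Kaplan–Meier curves and
the two-sided log-rank test, and reports the ratio of the two survival
estimates at the median follow-up time. A constant predictor yields a
single flagged group.

## Problem sizes used in the checks

The shipped tests run phantoms at 20³–48³ voxels, registration recovery at
48³, the selection-protocol calibration at n = 400 patients (1000
replicates for the null likelihood-ratio calibration), and survival
calibration at n = 200 with 50 power / 1000 null replicates — sizes chosen
so each property is measured with comfortable Monte-Carlo margin while the
whole suite stays desk-scale. Cross-validated headline performance on the
real trial (AUC/C-statistic on I-SPY 1 images) is out of scope: that data
is not redistributable, and the simulated cohort's feature distributions
make no claim to reproduce it.

## Known limitations

* The attribute set and saliency neighborhood are explicit simplified
  stand-ins, not reconstructions of the published attribute-matching
  registration; registration accuracy claims hold for the textured
  phantoms only.
* The entropy index depends on the bin count; 32 bins is a convention,
  not an estimate of an optimal discretization.
* The exponential RFS model has constant baseline hazard; the protocol's
  Cox machinery does not depend on that choice, but simulated effect
  sizes translate to event counts through it.
* FTV segmentation thresholds are nominal; absolute FTV values from the
  phantom should not be compared to published volumes.
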