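# dcetrack

Voxel-wise longitudinal analysis of dynamic contrast-enhanced breast MRI
(DCE-MRI) for early prediction of neoadjuvant-chemotherapy outcomes.

Women with locally advanced breast cancer are imaged before treatment and
again after the first chemotherapy cycle.  Registering the early-treatment
scan to the pre-treatment scan voxel-by-voxel lets two families of
within-tumor change maps be computed, instead of only whole-tumor
aggregates:

* **Deformation maps** from the transform T(x) = x + u(x).  With
  λ1 ≥ λ2 ≥ λ3 the principal stretches of ∇T,
  - Jacobian `J = λ1·λ2·λ3` — local volume ratio (J > 1 expansion,
    J < 1 contraction),
  - anisotropic deformation index
    `ADI = sqrt(((λ1−λ2)/λ2)² + ((λ2−λ3)/λ3)²)` — magnitude of
    non-shape-preserving deformation,
  - slab-rod index `SRI = atan(λ3(λ1−λ2)/(λ2(λ2−λ3)))/(π/2)` ∈ [0, 1] —
    rod-like (→1) versus slab-like (→0) anisotropy.
* **Parametric response maps (PRMs)** of per-voxel kinetic features
  PE, WIS, WOS, SER from the three-timepoint enhancement curve:
  `PRM(x) = J(x)·F_early(T(x)) − F_pre(x)`.

Each tumor is collapsed to **7 voxel-wise heterogeneity indices** (fraction
of increasing voxels for Jacobian and the four PRMs; histogram entropy of
ADI and SRI) plus **5 aggregate analogues** (FTV₂/FTV₁ and
`Δ_f = (f_early − f_pre)/f_early` for each kinetic feature's tumor mean).
These feed a cross-validated outcome-modeling protocol: logistic regression
for pathologic complete response (pCR, scored by AUC) and Cox regression
for recurrence-free survival (RFS, scored by Harrell's C), with per-fold
univariable ranking, nested best-subset selection by AIC, an 80%-consensus
refit compared to the baseline covariate model by likelihood-ratio test,
and median-split risk stratification with Kaplan–Meier/log-rank analysis.

Real trial images are not redistributable, so the package ships a phantom
generator producing paired-visit studies with analytic ground truth (known
deformation field, stretches, kinetic change) and a cohort simulator drawing
outcomes from known logistic and proportional-hazards models — every stage
is testable against closed-form or generating-model truth.

## Worked example

```python
import numpy as np
import dcetrack as dt

# a paired-visit phantom: 8% contraction of the tumor plus a kinetic drop
cfg = dt.RunConfig(out_dir="runs/demo", grid_shape=(32, 32, 32),
                   reg_max_iter=40, seed=0)
out = dt.run_pipeline(cfg)

import pandas as pd
print(pd.read_csv(out / "summaries.csv").T)
```

prints (one simulated tumor; your exact registration-dependent digits may
differ in the last places):

```
id                P0000
frac_jacobian  0.449947   # <0.5: most tumor voxels contracted
frac_PRM_PE    0.410959   # fewer than half the voxels gained enhancement
frac_PRM_WIS   0.410959
frac_PRM_WOS    0.56902
frac_PRM_SER   0.438356
entropy_ADI   -4.319423   # as-printed entropy (≤0; 0 = homogeneous map)
entropy_SRI   -4.907529
ftv_ratio      0.483667   # functional tumor volume halved
d_PE          -0.239595   # mean peak enhancement dropped
d_WIS         -0.239595
d_WOS         -0.036214
d_SER          0.139161
ftv1_cm3       3.202875
ftv2_cm3       1.549125
```

The deformation was a contracting affine map, so `frac_jacobian < 0.5` and
`ftv_ratio < 1`; the early-visit enhancement curve was weakened, so
`d_PE < 0` and most PRM fractions sit below one half.

Cohort-level modeling on simulated outcomes:

```python
table = dt.simulate_cohort(dt.CohortSpec(
    n_patients=400, log_odds={"frac_jacobian": np.log(3)}, seed=7))
report = dt.cv_select(table, dt.BASELINE_COVARIATES,
                      list(dt.VOXELWISE_FEATURES), "logistic", seed=8)
full, base, lrt_p = dt.consensus_refit(report, table,
                                       dt.BASELINE_COVARIATES, "logistic")
print(report.selection_counts["frac_jacobian"], lrt_p < 0.05)  # -> 5 True
```

The feature carrying the simulated odds ratio of 3 per SD is selected in
all five folds and the consensus model beats the baseline by likelihood
ratio.

A CLI mirrors the stages: `dcetrack simulate | preprocess | register |
deform-features | kinetics | model | run` (see `dcetrack --help`).

## Layout

```
src/dcetrack/
  grids.py           # VolumeGrid / DisplacementField / DCEStudy + NIfTI I/O
  phantom.py         # paired-visit phantom + cohort simulator
  preprocess.py      # bias correction, histogram matching, resampling
  register.py        # attribute cost, mutual saliency, baseline registration
  deform_features.py # Jacobian / ADI / SRI
  kinetics.py        # PE/WIS/WOS/SER, FTV segmentation, PRMs, aggregates
  summaries.py       # per-tumor 7 + 5 feature vector
  outcome_models.py  # fits, AUC / Harrell's C, CV selection, stratification
  pipeline.py, cli.py
docs/methods.md      # model and design notes
```
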