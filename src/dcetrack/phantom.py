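"""Synthetic paired-visit DCE phantoms and simulated outcome cohorts.

The phantom emulates the study design this pipeline targets: a pre-treatment
breast DCE-MRI visit and an early-treatment visit acquired after one
chemotherapy cycle, related by a smooth invertible tissue deformation and by
a change in the tumor's contrast-enhancement kinetics.  Everything downstream
(registration, deformation features, parametric response maps, outcome
models) is testable against this generator's analytic ground truth.

Geometry: the tumor is an ellipsoid with a smooth sigmoid boundary; the
inter-visit deformation is an affine map about the tumor center composed
with optional Gaussian-bump perturbations, so the analytic transform
gradient — and hence the true Jacobian and principal stretches — is
available in closed form at every voxel.

Intensity: each tissue class follows a three-timepoint enhancement curve
(values at t0, t1, t2 relative to contrast injection); voxel intensity is
the tissue-fraction blend of the class curves.  The early visit modifies the
tumor curve, then applies a smooth multiplicative bias field and additive
Gaussian noise.

The cohort simulator draws per-patient imaging features, demographic
covariates matching the target trial population, and outcomes from known
logistic (pathologic complete response) and proportional-hazards
(recurrence-free survival) models, with independent uniform administrative
censoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, optimize

from .grids import DCEStudy, DisplacementField, StretchMap, VolumeGrid

#: Names of the 7 voxel-wise heterogeneity indices in canonical order.
VOXELWISE_FEATURES = (
    "frac_jacobian",
    "frac_PRM_PE",
    "frac_PRM_WIS",
    "frac_PRM_WOS",
    "frac_PRM_SER",
    "entropy_ADI",
    "entropy_SRI",
)

#: Names of the 5 aggregate longitudinal features in canonical order.
AGGREGATE_FEATURES = ("ftv_ratio", "d_PE", "d_WIS", "d_WOS", "d_SER")

ALL_FEATURES = VOXELWISE_FEATURES + AGGREGATE_FEATURES


# ---------------------------------------------------------------------------
# Deformation model
# ---------------------------------------------------------------------------

@dataclass
class GaussianBump:
    """A localized smooth displacement a·exp(-|x-c|²/(2σ²)), all in mm."""

    center_mm: np.ndarray
    width_mm: float
    amplitude_mm: np.ndarray

    def __post_init__(self):
        self.center_mm = np.asarray(self.center_mm, dtype=float).reshape(3)
        self.amplitude_mm = np.asarray(self.amplitude_mm, dtype=float).reshape(3)
        if self.width_mm <= 0:
            raise ValueError("bump width must be > 0")


@dataclass
class DeformationSpec:
    """Forward (pre -> early) transform: affine about a center plus bumps.

    T(x) = center + A (x - center) + translation + Σ_k bump_k(x).
    """

    affine: np.ndarray = None  # type: ignore[assignment]
    translation_mm: np.ndarray = None  # type: ignore[assignment]
    center_mm: np.ndarray = None  # type: ignore[assignment]
    bumps: list[GaussianBump] = field(default_factory=list)

    def __post_init__(self):
        if self.affine is None:
            self.affine = np.eye(3)
        self.affine = np.asarray(self.affine, dtype=float).reshape(3, 3)
        if self.translation_mm is None:
            self.translation_mm = np.zeros(3)
        self.translation_mm = np.asarray(self.translation_mm, dtype=float).reshape(3)
        if self.center_mm is None:
            self.center_mm = np.zeros(3)
        self.center_mm = np.asarray(self.center_mm, dtype=float).reshape(3)

    def apply(self, pts: np.ndarray) -> np.ndarray:
        """T at world points (..., 3)."""
        pts = np.asarray(pts, dtype=float)
        rel = pts - self.center_mm
        out = self.center_mm + rel @ self.affine.T + self.translation_mm
        for b in self.bumps:
            d2 = np.sum((pts - b.center_mm) ** 2, axis=-1, keepdims=True)
            out = out + b.amplitude_mm * np.exp(-d2 / (2 * b.width_mm**2))
        return out

    def gradient(self, pts: np.ndarray) -> np.ndarray:
        """Analytic ∇T at world points: (..., 3, 3), ∂T_i/∂x_j."""
        pts = np.asarray(pts, dtype=float)
        g = np.broadcast_to(self.affine, pts.shape[:-1] + (3, 3)).copy()
        for b in self.bumps:
            diff = pts - b.center_mm
            d2 = np.sum(diff**2, axis=-1)
            w = np.exp(-d2 / (2 * b.width_mm**2)) / b.width_mm**2
            # ∂/∂x_j [a_i exp(.)] = -a_i (x_j - c_j)/σ² exp(.)
            g = g - b.amplitude_mm[..., None, :, None] * diff[..., None, :] * w[..., None, None]
        return g


# ---------------------------------------------------------------------------
# Phantom specification
# ---------------------------------------------------------------------------

@dataclass
class PhantomSpec:
    """Everything needed to synthesize one paired-visit phantom.

    Enhancement curves are (t0, t1, t2) intensity triples per tissue class;
    ``tumor_enhancement_early`` is the tumor's curve at the early visit
    (defaults to the pre-visit curve, i.e. no kinetic change).  Baseline
    (t0) intensities of tumor and background are kept equal so the blended
    kinetic features are linear in tumor fraction and the ground-truth
    kinetic deltas are exact.
    """

    grid_shape: tuple[int, int, int] = (48, 48, 48)
    spacing_mm: tuple[float, float, float] = (1.5, 1.5, 1.5)
    tumor_center_mm: np.ndarray = None  # type: ignore[assignment]
    tumor_radii_mm: np.ndarray = None  # type: ignore[assignment]
    boundary_width_mm: float = 1.5
    background_intensity: tuple[float, float, float] = (100.0, 105.0, 110.0)
    tumor_enhancement: tuple[float, float, float] = (100.0, 220.0, 180.0)
    tumor_enhancement_early: tuple[float, float, float] = None  # type: ignore[assignment]
    times_min: tuple[float, float, float] = (0.0, 2.5, 7.5)
    deformation: DeformationSpec = None  # type: ignore[assignment]
    noise_sd: float = 1.0
    bias_amplitude: float = 0.1
    bias_length_mm: float = 40.0
    seed: int = 0

    def __post_init__(self):
        self.grid_shape = tuple(int(n) for n in self.grid_shape)
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing_mm must be > 0 per axis")
        extent = np.array(self.grid_shape) * np.array(self.spacing_mm)
        if self.tumor_center_mm is None:
            self.tumor_center_mm = extent / 2
        self.tumor_center_mm = np.asarray(self.tumor_center_mm, dtype=float).reshape(3)
        if self.tumor_radii_mm is None:
            self.tumor_radii_mm = extent / 5
        self.tumor_radii_mm = np.asarray(self.tumor_radii_mm, dtype=float).reshape(3)
        if self.tumor_enhancement_early is None:
            self.tumor_enhancement_early = tuple(self.tumor_enhancement)
        if self.deformation is None:
            self.deformation = DeformationSpec(center_mm=self.tumor_center_mm)

    def grid(self) -> VolumeGrid:
        return VolumeGrid(np.zeros(self.grid_shape), np.array(self.spacing_mm))


@dataclass
class PhantomTruth:
    """Analytic ground truth on the pre-treatment grid."""

    true_displacement: DisplacementField
    true_stretches: StretchMap
    true_jacobian: np.ndarray
    true_kinetic_delta: dict[str, np.ndarray]
    tumor_mask: np.ndarray
    tumor_fraction: np.ndarray


def _tumor_fraction(spec: PhantomSpec, pts: np.ndarray) -> np.ndarray:
    """Smooth in-tumor fraction: sigmoid of signed distance to the ellipsoid."""
    rel = (pts - spec.tumor_center_mm) / spec.tumor_radii_mm
    r = np.sqrt(np.sum(rel**2, axis=-1))
    # approximate signed distance in mm from the normalized radius
    scale = float(np.mean(spec.tumor_radii_mm))
    return 1.0 / (1.0 + np.exp((r - 1.0) * scale / max(spec.boundary_width_mm, 1e-9)))


def _intensity(spec: PhantomSpec, pts: np.ndarray, tidx: int, early: bool) -> np.ndarray:
    frac = _tumor_fraction(spec, pts)
    bg = spec.background_intensity[tidx]
    tu = (spec.tumor_enhancement_early if early else spec.tumor_enhancement)[tidx]
    return bg * (1 - frac) + tu * frac


def _curve_kinetics(curve, times) -> dict[str, float]:
    """PE/WIS/WOS/SER of a three-point enhancement curve (no guards needed
    for well-formed phantom curves)."""
    i0, i1, i2 = (float(v) for v in curve)
    t0, t1, t2 = times
    e1, e2 = (i1 - i0) / i0, (i2 - i0) / i0
    pe = max(e1, e2)
    t_pe = t1 if e1 >= e2 else t2
    wis = pe / (t_pe - t0) if pe > 0 else 0.0
    wos = (i2 - i1) / (t2 - t_pe) if t2 != t_pe else 0.0
    ser = (i2 - i0) / (i1 - i0) if abs(i1 - i0) > 1e-3 * abs(i0) else 0.0
    return {"PE": pe, "WIS": wis, "WOS": wos, "SER": ser}


def _bias_field(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Smooth strictly positive multiplicative field, unit mean."""
    if spec.bias_amplitude == 0:
        return np.ones(spec.grid_shape)
    white = rng.standard_normal(spec.grid_shape)
    sigma_vox = spec.bias_length_mm / np.array(spec.spacing_mm)
    smooth = ndimage.gaussian_filter(white, sigma=sigma_vox, mode="nearest")
    peak = np.max(np.abs(smooth))
    if peak < 1e-12:
        return np.ones(spec.grid_shape)
    logf = spec.bias_amplitude * smooth / peak
    fieldv = np.exp(logf)
    return fieldv / fieldv.mean()


def invert_displacement(
    fwd: DisplacementField,
    tol_voxel: float = 1e-3,
    max_iter: int = 50,
    forward_fn=None,
) -> np.ndarray:
    """Fixed-point inverse of T(x) = x + u(x) at every grid voxel.

    Returns the pre-image points x such that T(x) = y for each grid voxel
    center y, as an (nx, ny, nz, 3) world-coordinate array.  ``forward_fn``
    may supply the analytic displacement at arbitrary points; otherwise the
    discrete field is linearly interpolated.
    """
    gridv = fwd.grid()
    y = gridv.world_coordinates()
    if forward_fn is None:
        comps = [fwd.u[..., a] for a in range(3)]

        def disp(pts):
            idx = gridv.world_to_index(pts)
            from .grids import sample_index

            return np.stack([sample_index(c, idx, "linear") for c in comps], axis=-1)
    else:
        disp = forward_fn

    x = y - disp(y)  # first-order guess
    tol_mm = tol_voxel * float(np.min(fwd.spacing_mm))
    for _ in range(max_iter):
        x_new = y - disp(x)
        move = np.max(np.linalg.norm(x_new - x, axis=-1))
        x = x_new
        if move < tol_mm:
            break
    return x


def make_study_pair(spec: PhantomSpec) -> tuple[DCEStudy, DCEStudy, PhantomTruth]:
    """Synthesize a pre-treatment / early-treatment study pair with truth.

    The early visit is the pre-visit tissue model carried through the forward
    deformation (synthesized by evaluating the analytic model at the
    fixed-point inverse of each early voxel), with the tumor enhancement
    curve switched to its early-visit values, then degraded by a smooth
    multiplicative bias field and additive Gaussian noise.  Identical specs
    and seeds give bit-identical output.

    Raises
    ------
    ValueError
        If the analytic Jacobian of the composed deformation is not strictly
        positive at every grid voxel (the deformation would fold).
    """
    gridv = spec.grid()
    pts = gridv.world_coordinates()

    gradT = spec.deformation.gradient(pts)
    detJ = np.linalg.det(gradT)
    if np.any(detJ <= 0):
        raise ValueError(
            "deformation spec has nonpositive analytic Jacobian on the grid "
            f"(min det = {detJ.min():.4g}); reduce bump amplitudes"
        )

    # ground truth on the pre grid
    u = spec.deformation.apply(pts) - pts
    disp = DisplacementField(u, np.array(spec.spacing_mm), gridv.origin_mm)
    sv = np.linalg.svd(gradT, compute_uv=False)  # sorted descending
    stretches = StretchMap(sv, np.ones(spec.grid_shape, dtype=bool),
                           np.array(spec.spacing_mm), gridv.origin_mm)
    frac = _tumor_fraction(spec, pts)
    mask = frac > 0.5

    kin_pre = _curve_kinetics(spec.tumor_enhancement, spec.times_min)
    kin_early = _curve_kinetics(spec.tumor_enhancement_early, spec.times_min)
    delta = {k: frac * (kin_early[k] - kin_pre[k]) for k in kin_pre}

    truth = PhantomTruth(disp, stretches, detJ, delta, mask, frac)

    # pre-visit volumes (clean tissue model, no degradation at visit 1)
    pre_vols = [gridv.like(_intensity(spec, pts, t, early=False)) for t in range(3)]
    pre = DCEStudy(*pre_vols, times_min=tuple(spec.times_min))

    # early-visit volumes via the analytic fixed-point inverse
    if _is_identity(spec.deformation):
        x_pre = pts
    else:
        x_pre = invert_displacement(disp, forward_fn=lambda p: spec.deformation.apply(p) - p)

    rng = np.random.default_rng(spec.seed)
    bias = _bias_field(spec, rng)
    early_vols = []
    for t in range(3):
        clean = _intensity(spec, x_pre, t, early=True)
        noisy = clean * bias + spec.noise_sd * rng.standard_normal(spec.grid_shape)
        early_vols.append(gridv.like(noisy))
    early = DCEStudy(*early_vols, times_min=tuple(spec.times_min))

    return pre, early, truth


def _is_identity(d: DeformationSpec) -> bool:
    return (
        not d.bumps
        and np.allclose(d.affine, np.eye(3))
        and np.allclose(d.translation_mm, 0)
    )


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

@dataclass
class CohortSpec:
    """Generating model for a simulated patient cohort.

    Effect coefficients are per-feature log-odds (pCR model) and log-hazard
    (RFS model) weights applied to the standardized features; unlisted
    features get zero effect.  Demographic distributions default to the
    target trial population (age 47.9 ± 8.9 years; 74.2% white-or-Hispanic;
    hormone-receptor classes HR+/HER2−, HER2+, triple-negative at
    38.6/37.1/24.3%).  ``baseline_event_rate`` is the pCR probability at the
    covariate baseline; RFS times are exponential with baseline hazard
    ``rfs_baseline_hazard`` per year and are administratively censored by an
    independent Uniform(0, H) time, H solved so the expected censored
    fraction equals ``censor_rate``.
    """

    n_patients: int = 132
    log_odds: dict[str, float] = field(default_factory=dict)
    log_hazard: dict[str, float] = field(default_factory=dict)
    baseline_event_rate: float = 0.30
    censor_rate: float = 0.705
    rfs_baseline_hazard: float = 0.12  # events / year at baseline
    age_mean: float = 47.87
    age_sd: float = 8.9
    race_prevalence: float = 0.742  # white-or-Hispanic
    hormone_probs: tuple[float, float, float] = (0.386, 0.371, 0.243)
    pcr_missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_patients < 2:
            raise ValueError("n_patients must be >= 2")
        if not 0 <= self.censor_rate <= 1:
            raise ValueError("censor_rate must be in [0, 1]")
        for d in (self.log_odds, self.log_hazard):
            for k, v in d.items():
                if not np.isfinite(v):
                    raise ValueError(f"non-finite effect coefficient for {k!r}")


def gaussian_feature_generator(rng: np.random.Generator, n: int) -> pd.DataFrame:
    """Default parametric feature model: independent standard normals for
    the 7 voxel-wise and 5 aggregate features (already standardized)."""
    data = {name: rng.standard_normal(n) for name in ALL_FEATURES}
    return pd.DataFrame(data)


def _solve_censor_horizon(times: np.ndarray, censor_rate: float) -> float:
    """Horizon H of Uniform(0, H) censoring giving the target censored
    fraction in expectation: E[P(C < T)] with C ⟂ T."""
    if censor_rate <= 0:
        return np.inf
    if censor_rate >= 1:
        return 0.0

    def frac_censored(h):
        # P(C < t) for C ~ U(0, h) = min(t/h, 1)
        return float(np.mean(np.minimum(times / h, 1.0))) - censor_rate

    lo, hi = 1e-6, float(times.max()) * 1e3
    if frac_censored(hi) > 0:  # even huge horizons censor too much (degenerate)
        return hi
    return float(optimize.brentq(frac_censored, lo, hi))


def simulate_cohort(cspec: CohortSpec, feature_generator=gaussian_feature_generator) -> pd.DataFrame:
    """Simulate a cohort table with covariates, imaging features, outcomes.

    pCR is Bernoulli with logit = logit(baseline_event_rate) + Σ β_f z_f;
    RFS time is exponential with hazard = rfs_baseline_hazard · exp(Σ γ_f z_f),
    right-censored by an independent uniform administrative time.
    """
    rng = np.random.default_rng(cspec.seed)
    n = cspec.n_patients

    feats = feature_generator(rng, n).reset_index(drop=True)
    missing = set(ALL_FEATURES) - set(feats.columns)
    if missing:
        raise ValueError(f"feature_generator missing columns: {sorted(missing)}")

    age = rng.normal(cspec.age_mean, cspec.age_sd, n)
    race = (rng.random(n) < cspec.race_prevalence).astype(int)
    hormone = rng.choice([1, 2, 3], size=n, p=np.asarray(cspec.hormone_probs))
    ftv1 = np.exp(rng.normal(np.log(35.0), 0.6, n))  # cm^3, log-normal volumes
    ftv2 = ftv1 * np.exp(rng.normal(-0.2, 0.4, n))

    def linpred(coeffs):
        lp = np.zeros(n)
        for name, beta in coeffs.items():
            if name not in feats.columns:
                raise KeyError(f"unknown feature in effect coefficients: {name!r}")
            lp += beta * feats[name].to_numpy()
        return lp

    # pCR from a logistic model
    logit0 = np.log(cspec.baseline_event_rate / (1 - cspec.baseline_event_rate))
    p = 1.0 / (1.0 + np.exp(-(logit0 + linpred(cspec.log_odds))))
    pcr = (rng.random(n) < p).astype(float)
    if cspec.pcr_missing_rate > 0:
        pcr[rng.random(n) < cspec.pcr_missing_rate] = np.nan

    # RFS from an exponential proportional-hazards model
    haz = cspec.rfs_baseline_hazard * np.exp(linpred(cspec.log_hazard))
    t_event = rng.exponential(1.0 / haz)
    horizon = _solve_censor_horizon(t_event, cspec.censor_rate)
    if np.isinf(horizon):
        rfs_time, rfs_event = t_event, np.ones(n, dtype=int)
    else:
        c = rng.uniform(0.0, max(horizon, 1e-9), n)
        rfs_event = (t_event <= c).astype(int)
        rfs_time = np.minimum(t_event, c)
    rfs_time = np.maximum(rfs_time, 1e-9)  # rfs_time > 0 invariant

    table = pd.DataFrame(
        {
            "id": [f"P{i:04d}" for i in range(n)],
            "age": age,
            "race": race,
            "hormone_status": hormone,
            "ftv1_cm3": ftv1,
            "ftv2_cm3": ftv2,
        }
    )
    for name in ALL_FEATURES:
        table[name] = feats[name].to_numpy()
    table["pcr"] = pcr
    table["rfs_time"] = rfs_time
    table["rfs_event"] = rfs_event
    return table
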