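"""End-to-end orchestration: phantom -> preprocess -> register -> feature
maps -> per-tumor summaries -> cohort outcome models.

A single ``RunConfig`` (YAML-serializable, round-trip stable) governs every
stage; ``run_pipeline`` executes the enabled stages in order into a run
directory, writing NIfTI maps, the per-tumor summaries CSV, JSON model
reports and a JSON-lines log carrying provenance (config hash, seed,
package versions).  Stage outputs are pure functions of (inputs, config,
seed): rerunning an identical config reproduces the summaries CSV
bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import deform_features, kinetics, outcome_models, preprocess, register, summaries
from .grids import DisplacementField, save_displacement, save_volume
from .phantom import (
    ALL_FEATURES,
    CohortSpec,
    DeformationSpec,
    GaussianBump,
    PhantomSpec,
    make_study_pair,
    simulate_cohort,
)


@dataclass
class RunConfig:
    """All pipeline parameters in one serializable record."""

    out_dir: str = "runs/default"
    seed: int = 0

    # stage toggles
    run_phantom: bool = True
    run_preprocess: bool = True
    run_register: bool = True
    run_features: bool = True
    run_summarize: bool = True
    run_model: bool = False

    # phantom
    grid_shape: tuple[int, int, int] = (48, 48, 48)
    spacing_mm: tuple[float, float, float] = (1.5, 1.5, 1.5)
    affine_scale: tuple[float, float, float] = (0.92, 0.95, 0.97)
    translation_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    bump_amplitude_mm: float = 0.0
    bump_width_mm: float = 10.0
    noise_sd: float = 1.0
    bias_amplitude: float = 0.1
    tumor_enhancement: tuple[float, float, float] = (100.0, 220.0, 180.0)
    tumor_enhancement_early: tuple[float, float, float] = (100.0, 190.0, 170.0)

    # preprocess
    bias_smoothness_mm: float = 30.0
    n_quantiles: int = 256
    target_spacing_mm: tuple[float, float, float] | None = None
    interp: str = "linear"

    # registration
    registration_mode: str = "baseline"  # or "truth" to reuse the phantom field
    reg_levels: int = 3
    reg_alpha: float = 0.1
    reg_max_iter: int = 60
    reg_scales_mm: tuple[float, ...] = (1.5, 3.0)

    # FTV segmentation
    pe_min: float = 0.7
    ser_range: tuple[float, float] = (0.0, float("inf"))

    # summaries
    entropy_bins: int = 32
    entropy_convention: str = "as_printed"
    prm_deadband: float = 0.0
    stretch_mode: str = "singular_values"
    wis_condition: str = "interpreted"
    wos_denominator: str = "t2_minus_tpe"

    # outcome modeling
    n_patients: int = 132
    cv_folds: int = 5
    feature_set: str = "voxelwise"  # voxelwise | aggregate
    outcome: str = "pcr"  # pcr | rfs
    log_odds: dict = field(default_factory=dict)
    log_hazard: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return json.loads(json.dumps(d))  # tuples -> lists, plain types only

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name not in d:
                continue
            v = d[f.name]
            if isinstance(v, list):
                v = tuple(v)
            kwargs[f.name] = v
        return cls(**kwargs)

    def config_hash(self) -> str:
        return hashlib.sha256(
            yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and the offending input."""

    def __init__(self, stage: str, detail: str):
        super().__init__(f"pipeline stage {stage!r} failed: {detail}")
        self.stage = stage
        self.detail = detail


class _Log:
    def __init__(self, path: Path):
        self.path = path
        self.path.write_text("")

    def event(self, stage: str, **info) -> None:
        rec = {"stage": stage, **info}
        with self.path.open("a") as fh:
            fh.write(json.dumps(rec, default=str) + "\n")


def _phantom_spec(cfg: RunConfig) -> PhantomSpec:
    deformation = DeformationSpec(
        affine=np.diag(cfg.affine_scale),
        translation_mm=np.array(cfg.translation_mm),
        center_mm=None,  # set below, around the tumor
    )
    spec = PhantomSpec(
        grid_shape=cfg.grid_shape,
        spacing_mm=cfg.spacing_mm,
        noise_sd=cfg.noise_sd,
        bias_amplitude=cfg.bias_amplitude,
        tumor_enhancement=cfg.tumor_enhancement,
        tumor_enhancement_early=cfg.tumor_enhancement_early,
        seed=cfg.seed,
    )
    deformation.center_mm = spec.tumor_center_mm.copy()
    if cfg.bump_amplitude_mm != 0.0:
        offset = np.array([spec.tumor_radii_mm[0], 0.0, 0.0])
        deformation.bumps.append(
            GaussianBump(spec.tumor_center_mm + offset, cfg.bump_width_mm,
                         np.array([cfg.bump_amplitude_mm, 0.0, 0.0]))
        )
    spec.deformation = deformation
    return spec


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute the enabled stages in order; returns the run directory."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg.save(out / "config.yaml")
    log = _Log(out / "log.jsonl")
    versions = {m.__name__: m.__version__ for m in (np, pd)}
    log.event("start", config_hash=cfg.config_hash(), seed=cfg.seed,
              versions=versions, time=time.strftime("%Y-%m-%dT%H:%M:%S"))

    pre = early = truth = None
    disp = None

    if cfg.run_phantom:
        try:
            spec = _phantom_spec(cfg)
            pre, early, truth = make_study_pair(spec)
        except Exception as exc:
            log.event("phantom", error=str(exc))
            raise PipelineError("phantom", str(exc)) from exc
        for tag, study in (("pre", pre), ("early", early)):
            for ti, vol in enumerate(study.volumes()):
                save_volume(vol, out / f"{tag}_t{ti}.nii.gz")
        save_displacement(truth.true_displacement, out / "true_displacement.nii.gz")
        save_volume(pre.grid.like(truth.tumor_mask.astype(float)), out / "tumor_mask.nii.gz")
        log.event("phantom", grid=list(cfg.grid_shape), n_tumor=int(truth.tumor_mask.sum()))

    reg_moving = None  # histogram-matched early t1 volume, registration input only
    if cfg.run_preprocess:
        if early is None:
            raise PipelineError("preprocess", "no input studies (enable phantom stage)")
        try:
            corrected = []
            for ti, vol in enumerate(early.volumes()):
                cvol, fieldv = preprocess.correct_bias(vol, cfg.bias_smoothness_mm)
                if cfg.target_spacing_mm is not None:
                    cvol = preprocess.resample(cvol, cfg.target_spacing_mm, cfg.interp)
                corrected.append(cvol)
                save_volume(cvol, out / f"early_t{ti}_preproc.nii.gz")
            early = kinetics.DCEStudy(*corrected, times_min=early.times_min)
            # histogram matching aligns the two visits' intensity scales for
            # the registration cost; kinetic features keep the unmatched
            # (bias-corrected) intensities so longitudinal change survives
            reg_moving = preprocess.match_histogram(early.vol_t1, pre.vol_t1,
                                                    cfg.n_quantiles)
        except Exception as exc:
            log.event("preprocess", error=str(exc))
            raise PipelineError("preprocess", str(exc)) from exc
        log.event("preprocess", smoothness_mm=cfg.bias_smoothness_mm,
                  quantiles=cfg.n_quantiles)

    if cfg.run_register:
        try:
            if cfg.registration_mode == "truth":
                if truth is None:
                    raise ValueError("truth registration mode requires the phantom stage")
                disp = truth.true_displacement
                reg_info = {"mode": "truth"}
            else:
                params = register.RegistrationParams(
                    levels=cfg.reg_levels, alpha=cfg.reg_alpha,
                    max_iter=cfg.reg_max_iter, scales_mm=cfg.reg_scales_mm,
                )
                moving_vol = reg_moving if reg_moving is not None else early.vol_t1
                result = register.register_baseline(pre.vol_t1, moving_vol, params)
                disp = result.field
                reg_info = {
                    "mode": "baseline",
                    "converged": result.converged,
                    "cost_initial": result.cost_initial,
                    "cost_final": result.cost_final,
                    "jacobian_positive_fraction": result.jacobian_positive_fraction,
                    "flags": result.flags,
                }
            save_displacement(disp, out / "displacement.nii.gz")
        except Exception as exc:
            log.event("register", error=str(exc))
            raise PipelineError("register", str(exc)) from exc
        log.event("register", **reg_info)

    summary = None
    if cfg.run_features or cfg.run_summarize:
        if pre is None or early is None or disp is None:
            raise PipelineError("features", "missing studies or displacement field")
        try:
            summary = extract_tumor_summary(pre, early, disp, cfg, out_dir=out if cfg.run_features else None)
        except Exception as exc:
            log.event("features", error=str(exc))
            raise PipelineError("features", str(exc)) from exc
        log.event("features", ftv1_cm3=summary.ftv1_cm3, ftv2_cm3=summary.ftv2_cm3)

    if cfg.run_summarize:
        row = {"id": "P0000", **summary.as_row()}
        df = pd.DataFrame([row])
        df.to_csv(out / "summaries.csv", index=False)
        (out / "summary_flags.json").write_text(
            json.dumps({"n_valid": summary.n_valid, "flags": summary.flags}, indent=2)
        )
        log.event("summarize", n_voxelwise=len(summary.voxelwise),
                  n_aggregate=len(summary.aggregate))

    if cfg.run_model:
        try:
            cspec = CohortSpec(n_patients=cfg.n_patients, log_odds=dict(cfg.log_odds),
                               log_hazard=dict(cfg.log_hazard), seed=cfg.seed)
            cohort = simulate_cohort(cspec)
            cohort.to_csv(out / "cohort.csv", index=False)
            family = "logistic" if cfg.outcome == "pcr" else "cox"
            cands = [f for f in ALL_FEATURES if f.startswith(("frac", "entropy"))] \
                if cfg.feature_set == "voxelwise" else \
                [f for f in ALL_FEATURES if not f.startswith(("frac", "entropy"))]
            report = outcome_models.cv_select(
                cohort, outcome_models.BASELINE_COVARIATES, cands, family,
                k=cfg.cv_folds, seed=cfg.seed,
            )
            full, base, lrt_p = outcome_models.consensus_refit(
                report, cohort, outcome_models.BASELINE_COVARIATES, family)
            rep = {
                "family": family,
                "mean_metric": report.mean_metric,
                "sd_metric": report.sd_metric,
                "selection_counts": report.selection_counts,
                "consensus": report.consensus(),
                "lrt_p": lrt_p,
                "full_coef": {k: float(v) for k, v in full.coef.items()},
                "baseline_coef": {k: float(v) for k, v in base.coef.items()},
                "full_aic": full.aic,
                "baseline_aic": base.aic,
            }
            (out / "model_report.json").write_text(json.dumps(rep, indent=2))
            if family == "cox":
                strat = outcome_models.risk_stratify(full, cohort)
                strat.km_low.to_csv(out / "km_low.csv", index=False)
                strat.km_high.to_csv(out / "km_high.csv", index=False)
                rep["logrank_p"] = strat.logrank_p
                rep["survival_ratio_at_median_time"] = strat.survival_ratio_at_median_time
                (out / "model_report.json").write_text(json.dumps(rep, indent=2))
        except Exception as exc:
            log.event("model", error=str(exc))
            raise PipelineError("model", str(exc)) from exc
        log.event("model", outcome=cfg.outcome, mean_metric=report.mean_metric,
                  lrt_p=lrt_p)

    log.event("done")
    return out


def extract_tumor_summary(
    pre,
    early,
    disp: DisplacementField,
    cfg: RunConfig | None = None,
    out_dir: Path | None = None,
) -> summaries.TumorSummary:
    """Feature-map extraction and per-tumor summary for one study pair.

    Segments FTV1/FTV2, computes the deformation maps from the displacement
    field, the kinetic and PRM maps, the five aggregates, and collapses
    everything to the 7 + 5 per-tumor feature vector.  Maps are written as
    NIfTI when ``out_dir`` is given.
    """
    if cfg is None:
        cfg = RunConfig()
    ftv1, ftv1_cm3 = kinetics.segment_ftv(pre, pe_min=cfg.pe_min, ser_range=cfg.ser_range)
    ftv2, ftv2_cm3 = kinetics.segment_ftv(early, pe_min=cfg.pe_min, ser_range=cfg.ser_range)
    if not ftv1.any():
        raise ValueError("empty FTV1; lower pe_min or check the phantom contrast")

    maps = deform_features.deformation_maps(disp, ftv1, cfg.stretch_mode)

    kin_pre = kinetics.kinetic_maps(pre, ftv1, cfg.wis_condition, cfg.wos_denominator)
    kin_early_full = kinetics.kinetic_maps(early, None, cfg.wis_condition, cfg.wos_denominator)
    early_vols = {
        name: early.grid.like(kin_early_full[name].values) for name in kinetics.KINETIC_NAMES
    }
    maps.update(kinetics.prm_maps(kin_pre, early_vols, disp, maps["Jacobian"]))

    kin_early_ftv2 = kinetics.kinetic_maps(early, ftv2, cfg.wis_condition, cfg.wos_denominator)
    aggregates = kinetics.aggregate_features(kin_pre, kin_early_ftv2, ftv1_cm3, ftv2_cm3)

    if out_dir is not None:
        from .grids import save_volume as _save

        for name, fm in maps.items():
            vol = pre.grid.like(np.where(fm.mask, fm.values, 0.0))
            _save(vol, Path(out_dir) / f"map_{name}.nii.gz")

    return summaries.summarize_tumor(
        maps, aggregates, ftv1_cm3, ftv2_cm3,
        entropy_bins=cfg.entropy_bins, entropy_convention=cfg.entropy_convention,
        prm_deadband=cfg.prm_deadband,
    )
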