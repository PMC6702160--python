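"""Per-voxel DCE kinetic features, FTV segmentation, PRMs, aggregates.

From a three-timepoint enhancement curve I(t0), I(t1), I(t2) (pre-contrast
plus two post-contrast acquisitions, times in minutes) four kinetic features
are computed per voxel:

* PE  — peak relative enhancement, max over post-contrast times of
        (I(t) - I(t0)) / I(t0), with t_PE the time of the peak (earliest on
        ties);
* WIS — wash-in slope PE / (t_PE - t0) when a positive enhancement peak
        exists, else 0;
* WOS — wash-out slope (I(t2) - I(t1)) / (t2 - t_PE) when t2 != t_PE,
        else 0 (implemented as printed; a (t2 - t1) denominator variant is
        available behind ``wos_denominator``);
* SER — signal enhancement ratio (I(t2) - I(t0)) / (I(t1) - I(t0)),
        guarded to 0 (and flagged) when the wash-in difference is below
        1e-3 relative to baseline.

Functional tumor volume (FTV) masks threshold PE and SER inside a region of
interest and keep the largest 26-connected component.  Parametric response
maps compare a feature between registered visits,
PRM(x) = J(x) * F_early(T(x)) - F_pre(x), with the Jacobian J compensating
the local volume change.  Aggregate analogues are the volume ratio
FTV2/FTV1 and the relative change of each feature's tumor mean,
Δ_f = (f_early - f_pre) / f_early.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .grids import DCEStudy, DisplacementField, FeatureMap, VolumeGrid

SER_GUARD_REL = 1e-3
T_PE_NONE = -1.0  # sentinel where no positive enhancement exists

KINETIC_NAMES = ("PE", "WIS", "WOS", "SER")


@dataclass
class KineticSet:
    """The four kinetic feature maps plus the per-voxel time of peak."""

    PE: FeatureMap
    WIS: FeatureMap
    WOS: FeatureMap
    SER: FeatureMap
    t_PE: np.ndarray  # minutes; T_PE_NONE where no positive enhancement

    def __getitem__(self, name: str) -> FeatureMap:
        if name not in KINETIC_NAMES:
            raise KeyError(name)
        return getattr(self, name)


def kinetic_maps(
    study: DCEStudy,
    mask: np.ndarray | None = None,
    wis_condition: str = "interpreted",
    wos_denominator: str = "t2_minus_tpe",
) -> KineticSet:
    """Compute PE, WIS, WOS and SER over the mask.

    ``wis_condition='interpreted'`` (default) grants a wash-in slope only
    when a positive enhancement peak exists at a post-contrast time;
    ``'literal'`` applies the printed condition t_PE != 0 minutes.  Voxels
    with nonpositive baseline intensity are flagged and get zero features.
    """
    if mask is None:
        mask = np.ones(study.grid.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    t0, t1, t2 = study.times_min
    i0 = study.vol_t0.values
    i1 = study.vol_t1.values
    i2 = study.vol_t2.values

    bad_baseline = (i0 <= 0) & mask
    i0s = np.where(i0 > 0, i0, 1.0)

    e1 = (i1 - i0) / i0s
    e2 = (i2 - i0) / i0s
    pe = np.maximum(e1, e2)
    t_pe = np.where(e1 >= e2, t1, t2)  # earliest on ties

    positive_peak = pe > 0
    t_pe_out = np.where(positive_peak, t_pe, T_PE_NONE)

    if wis_condition == "interpreted":
        wis_ok = positive_peak
    elif wis_condition == "literal":
        wis_ok = t_pe != 0
    else:
        raise ValueError(f"unknown wis_condition {wis_condition!r}")
    wis = np.where(wis_ok, pe / (t_pe - t0), 0.0)

    if wos_denominator == "t2_minus_tpe":
        wos_den = t2 - t_pe
    elif wos_denominator == "t2_minus_t1":
        wos_den = np.full_like(t_pe, t2 - t1)
    else:
        raise ValueError(f"unknown wos_denominator {wos_denominator!r}")
    wos = np.where(t_pe != t2, (i2 - i1) / np.where(wos_den != 0, wos_den, 1.0), 0.0)

    wash_in = i1 - i0
    ser_guarded = np.abs(wash_in) < SER_GUARD_REL * np.abs(i0s)
    ser = np.where(~ser_guarded, (i2 - i0) / np.where(ser_guarded, 1.0, wash_in), 0.0)

    flagged = bad_baseline
    for arr in (pe, wis, wos, ser):
        arr[flagged] = 0.0
    t_pe_out = np.where(flagged, T_PE_NONE, t_pe_out)
    valid = mask & ~flagged

    def fm(name, vals):
        m = FeatureMap(name, vals, mask, valid=valid)
        m.flags["bad_baseline"] = flagged
        return m

    out = KineticSet(fm("PE", pe), fm("WIS", wis), fm("WOS", wos), fm("SER", ser), t_pe_out)
    out.SER.flags["ser_guarded"] = ser_guarded & mask
    out.PE.flags["no_enhancement"] = mask & ~positive_peak
    return out


def segment_ftv(
    study: DCEStudy,
    roi_mask: np.ndarray | None = None,
    pe_min: float = 0.7,
    ser_range: tuple[float, float] = (0.0, np.inf),
    keep_largest: bool = True,
) -> tuple[np.ndarray, float]:
    """Enhancement-based functional tumor volume segmentation.

    Voxels in the ROI with PE >= pe_min and SER inside ``ser_range`` are
    kept; optionally only the largest 26-connected component survives.
    Returns (mask, volume_cm3).  An empty result warns instead of raising.
    """
    if roi_mask is None:
        roi_mask = np.ones(study.grid.shape, dtype=bool)
    roi_mask = np.asarray(roi_mask, dtype=bool)
    if not roi_mask.any():
        raise ValueError("roi_mask is empty")

    kin = kinetic_maps(study, roi_mask)
    lo, hi = ser_range
    sel = (
        roi_mask
        & kin.PE.valid
        & (kin.PE.values >= pe_min)
        & (kin.SER.values > lo)
        & (kin.SER.values < hi)
    )
    if keep_largest and sel.any():
        labels, n = ndimage.label(sel, structure=np.ones((3, 3, 3), dtype=int))
        if n > 1:
            sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
            sel = labels == (1 + int(np.argmax(sizes)))
    if not sel.any():
        warnings.warn("segment_ftv: empty functional tumor volume", RuntimeWarning,
                      stacklevel=2)
    vol_cm3 = float(sel.sum()) * study.grid.voxel_volume_mm3 / 1000.0
    return sel, vol_cm3


def prm_map(
    f_pre: FeatureMap,
    f_early: VolumeGrid,
    T: DisplacementField,
    jacobian: FeatureMap,
) -> FeatureMap:
    """Parametric response map PRM(x) = J(x) * F_early(T(x)) - F_pre(x).

    ``f_early`` is the early-visit feature on the early grid, sampled at the
    mapped points by linear interpolation; support is the pre-visit tumor
    mask.  Voxels mapped outside the early image are flagged and excluded
    from downstream summaries.
    """
    mask = f_pre.mask
    pts = T.mapped_points()
    lo = f_early.origin_mm
    hi = f_early.origin_mm + (np.array(f_early.shape) - 1) * f_early.spacing_mm
    inside = np.all((pts >= lo) & (pts <= hi), axis=-1)

    sampled = f_early.sample_world(pts, interp="linear")
    prm = jacobian.values * sampled - f_pre.values

    valid = mask & inside & f_pre.valid & jacobian.valid
    out = FeatureMap(f"PRM_{f_pre.name}", prm, mask, valid=valid)
    out.flags["outside_early"] = mask & ~inside
    return out


def prm_maps(
    kin_pre: KineticSet,
    early_feature_vols: dict[str, VolumeGrid],
    T: DisplacementField,
    jacobian: FeatureMap,
) -> dict[str, FeatureMap]:
    """PRM of all four kinetic features (keys PRM_PE, PRM_WIS, ...)."""
    return {
        f"PRM_{name}": prm_map(kin_pre[name], early_feature_vols[name], T, jacobian)
        for name in KINETIC_NAMES
    }


def aggregate_features(
    kin_pre: KineticSet,
    kin_early: KineticSet,
    ftv1_cm3: float,
    ftv2_cm3: float,
    eps: float = 1e-12,
) -> dict[str, float]:
    """The five aggregate longitudinal features.

    FTV2/FTV1 plus Δ_f = (f_early - f_pre) / f_early for each kinetic
    feature f, where the means are taken over each visit's own functional
    tumor volume.  Δ_f is NaN (flagged undefined) when the early mean is
    within ``eps`` of zero; an empty FTV2 yields volume ratio 0 and NaN
    deltas.
    """
    if ftv1_cm3 <= 0:
        raise ValueError("ftv1_cm3 must be > 0")
    out = {"ftv_ratio": ftv2_cm3 / ftv1_cm3 if ftv2_cm3 > 0 else 0.0}
    for name in KINETIC_NAMES:
        pre_vals = kin_pre[name].masked_values()
        early_vals = kin_early[name].masked_values()
        if early_vals.size == 0:
            out[f"d_{name}"] = np.nan
            continue
        f_pre = float(pre_vals.mean()) if pre_vals.size else np.nan
        f_early = float(early_vals.mean())
        out[f"d_{name}"] = (f_early - f_pre) / f_early if abs(f_early) > eps else np.nan
    return out
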