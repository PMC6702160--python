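"""Pre-processing: bias-field correction, histogram matching, resampling.

These are the three standardization steps applied before registration and
feature extraction: remove the smooth multiplicative intensity
non-uniformity that MR coils impose, match the intensity histograms of the
two visits so the registration cost compares like with like, and resample
volumes to a common spatial resolution.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .grids import VolumeGrid


def correct_bias(
    vol: VolumeGrid,
    smoothness_mm: float = 30.0,
    mask: np.ndarray | None = None,
    tol: float = 1e-4,
    max_iter: int = 20,
) -> tuple[VolumeGrid, VolumeGrid]:
    """Estimate and remove a smooth multiplicative bias field.

    The field is fit iteratively in the log-intensity domain: at each step
    the residual low-frequency log-field is estimated by Gaussian smoothing
    at ``smoothness_mm`` (mean-centered over the mask so only non-uniformity,
    not overall brightness, is attributed to bias) and accumulated, until the
    update falls below ``tol`` or ``max_iter`` iterations.  The returned
    field is strictly positive with mask-mean ≈ 1, and the corrected volume
    ``vol / field`` preserves the mask-mean intensity exactly.

    Returns
    -------
    (corrected, estimated_field) : tuple of VolumeGrid
    """
    if mask is None:
        mask = np.ones(vol.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    vals = vol.values
    if np.any(vals[mask] <= 0):
        raise ValueError("bias correction requires strictly positive intensities in the mask")

    sigma_vox = float(smoothness_mm) / vol.spacing_mm
    log_i = np.log(np.where(vals > 0, vals, 1.0))
    field_log = np.zeros_like(log_i)
    for _ in range(max_iter):
        resid = ndimage.gaussian_filter(log_i - field_log, sigma=sigma_vox, mode="nearest")
        resid = resid - resid[mask].mean()
        field_log += resid
        if np.max(np.abs(resid)) < tol:
            break

    fieldv = np.exp(field_log)
    corrected = vals / fieldv
    # preserve the mask-mean intensity exactly; fold the scalar into the field
    scale = vals[mask].mean() / corrected[mask].mean()
    corrected = corrected * scale
    fieldv = fieldv / scale
    return vol.like(corrected), vol.like(fieldv)


def match_histogram(
    moving: VolumeGrid,
    reference: VolumeGrid,
    n_quantiles: int = 256,
    mask: np.ndarray | None = None,
) -> VolumeGrid:
    """Remap ``moving`` by a monotone piecewise-linear quantile map so its
    empirical quantiles match the reference's.

    The map is built from ``n_quantiles`` matched quantile pairs (computed
    over ``mask`` if given, else the whole volume) and applied to every
    voxel; rank order is preserved.  A constant moving image maps to the
    reference median (any monotone convention works for a degenerate
    quantile function; this one is stable).
    """
    if n_quantiles < 2:
        raise ValueError("n_quantiles must be >= 2")
    if moving.values.size == 0 or reference.values.size == 0:
        raise ValueError("volumes must be nonempty")
    if mask is None:
        mov = moving.values.ravel()
        ref = reference.values.ravel()
    else:
        mask = np.asarray(mask, dtype=bool)
        mov = moving.values[mask]
        ref = reference.values[mask]

    qs = np.linspace(0.0, 1.0, int(n_quantiles))
    mq = np.quantile(mov, qs)
    rq = np.quantile(ref, qs)

    if mq[-1] - mq[0] < 1e-30:  # constant moving image
        out = np.full_like(moving.values, np.median(ref))
        return moving.like(out)

    # collapse duplicate knots so np.interp sees strictly increasing x
    uniq, inv = np.unique(mq, return_inverse=True)
    rq_u = np.zeros_like(uniq)
    counts = np.zeros_like(uniq)
    np.add.at(rq_u, inv, rq)
    np.add.at(counts, inv, 1.0)
    rq_u /= counts

    out = np.interp(moving.values, uniq, rq_u)
    return moving.like(out)


def resample(
    vol: VolumeGrid,
    target_spacing_mm,
    interp: str = "linear",
) -> VolumeGrid:
    """Resample onto a grid with the requested spacing over the same extent.

    The new grid keeps the input origin; its size is the rounded ratio of
    physical extent to new spacing (at least one voxel per axis).  Samples
    outside the input extent clamp to the nearest edge value.  Requesting the
    current spacing reproduces the input exactly.
    """
    target = np.asarray(target_spacing_mm, dtype=float).reshape(3)
    if np.any(target <= 0):
        raise ValueError("target_spacing_mm must be > 0")
    if interp not in ("linear", "nearest"):
        raise ValueError(f"unknown interp mode {interp!r}")

    extent = np.array(vol.shape) * vol.spacing_mm
    new_shape = np.maximum(1, np.round(extent / target).astype(int))
    newgrid = VolumeGrid(np.zeros(tuple(new_shape)), target, vol.origin_mm.copy())
    pts = newgrid.world_coordinates()
    vals = vol.sample_world(pts, interp=interp)
    return newgrid.like(vals)
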