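"""Voxel-wise deformation feature maps: Jacobian, ADI and SRI.

From the inter-visit transform T(x) = x + u(x), the local deformation at a
voxel is characterized by the principal stretches λ1 ≥ λ2 ≥ λ3 — the
singular values of the transform gradient ∇T.  Three scalar maps follow:

* Jacobian J = λ1 λ2 λ3 = det ∇T, the local volume ratio early/pre
  (J > 1 expansion, J < 1 contraction);
* the anisotropic deformation index
  ADI = sqrt(((λ1-λ2)/λ2)^2 + ((λ2-λ3)/λ3)^2) >= 0, zero iff the local
  deformation is isotropic (shape-preserving);
* the slab-rod index
  SRI = atan(λ3(λ1-λ2) / (λ2(λ2-λ3))) / (π/2) in [0, 1], distinguishing
  rod-like one-directional anisotropy (SRI -> 1, the λ2 = λ3 limit) from
  slab-like two-directional anisotropy (SRI -> 0, the λ1 = λ2 case).

λ are taken as singular values of ∇T rather than raw eigenvalues of
∇T(∇T)^T so that λ1λ2λ3 equals the volume ratio det ∇T exactly (the
eigenvalues of ∇T(∇T)^T would give its square); the eigenvalue mode is
available behind ``stretch_mode`` for comparison.
"""

from __future__ import annotations

import numpy as np

from .grids import DisplacementField, FeatureMap, StretchMap

EPS_CLAMP = 1e-8
_EPS_TIE = 1e-12


def displacement_gradient(T: DisplacementField) -> tuple[np.ndarray, np.ndarray]:
    """Transform gradient ∇T = I + ∇u at every voxel, world (mm) units.

    Central differences at interior voxels, one-sided on boundary faces;
    boundary voxels are flagged (returned mask False there).  Single-slice
    axes fall back to one-sided/zero differences and flag the whole grid.

    Returns
    -------
    gradT : (nx, ny, nz, 3, 3) array, ∂T_i/∂x_j
    interior : bool array, True where all three axes used central differences
    """
    u = T.u
    sp = T.spacing_mm
    shape = u.shape[:3]
    gradT = np.zeros(shape + (3, 3))
    interior = np.ones(shape, dtype=bool)
    for i in range(3):  # component
        for j in range(3):  # axis
            if shape[j] > 1:
                gradT[..., i, j] = np.gradient(u[..., i], sp[j], axis=j)
            # single-slice axis: derivative undefined, leave 0 and flag
        gradT[..., i, i] += 1.0
    for j in range(3):
        if shape[j] > 1:
            sl_lo = [slice(None)] * 3
            sl_hi = [slice(None)] * 3
            sl_lo[j] = 0
            sl_hi[j] = -1
            interior[tuple(sl_lo)] = False
            interior[tuple(sl_hi)] = False
        else:
            interior[:] = False
    return gradT, interior


def principal_stretches(
    gradT: np.ndarray,
    interior: np.ndarray | None = None,
    spacing_mm=None,
    origin_mm=None,
    stretch_mode: str = "singular_values",
) -> StretchMap:
    """Principal stretches per voxel, sorted λ1 ≥ λ2 ≥ λ3.

    ``stretch_mode='singular_values'`` (default) takes the singular values
    of ∇T; ``'eigenvalues'`` takes the raw eigenvalues of ∇T(∇T)^T (their
    product is det(∇T)^2, kept only for comparison).  Non-finite matrices
    flag the voxel invalid.
    """
    gradT = np.asarray(gradT, dtype=float)
    shape = gradT.shape[:-2]
    finite = np.all(np.isfinite(gradT), axis=(-2, -1))
    safe = np.where(finite[..., None, None], gradT, np.eye(3))

    if stretch_mode == "singular_values":
        lam = np.linalg.svd(safe, compute_uv=False)  # descending
    elif stretch_mode == "eigenvalues":
        b = safe @ np.swapaxes(safe, -1, -2)
        ev = np.linalg.eigvalsh(b)  # ascending
        lam = ev[..., ::-1]
    else:
        raise ValueError(f"unknown stretch_mode {stretch_mode!r}")

    valid = finite.copy()
    if interior is not None:
        valid &= interior
    sp = np.ones(3) if spacing_mm is None else np.asarray(spacing_mm, dtype=float)
    org = np.zeros(3) if origin_mm is None else np.asarray(origin_mm, dtype=float)
    return StretchMap(lam.reshape(shape + (3,)), valid.reshape(shape), sp, org)


def stretches_from_field(T: DisplacementField, stretch_mode: str = "singular_values") -> StretchMap:
    """Convenience: ∇T then principal stretches in one call."""
    gradT, interior = displacement_gradient(T)
    return principal_stretches(gradT, interior, T.spacing_mm, T.origin_mm, stretch_mode)


def jacobian_map(stretches: StretchMap, mask: np.ndarray | None = None) -> FeatureMap:
    """J = λ1 λ2 λ3: local volume ratio early/pre."""
    lam = stretches.lambdas
    j = lam[..., 0] * lam[..., 1] * lam[..., 2]
    if mask is None:
        mask = np.ones(j.shape, dtype=bool)
    return FeatureMap("Jacobian", j, mask, valid=stretches.valid & mask)


def adi_map(stretches: StretchMap, mask: np.ndarray | None = None) -> FeatureMap:
    """Anisotropic deformation index; λ2, λ3 clamped below at 1e-8."""
    lam = stretches.lambdas
    l1, l2, l3 = lam[..., 0], lam[..., 1], lam[..., 2]
    clamped = (l2 < EPS_CLAMP) | (l3 < EPS_CLAMP)
    l2c = np.maximum(l2, EPS_CLAMP)
    l3c = np.maximum(l3, EPS_CLAMP)
    adi = np.sqrt(((l1 - l2) / l2c) ** 2 + ((l2 - l3) / l3c) ** 2)
    if mask is None:
        mask = np.ones(adi.shape, dtype=bool)
    # clamped voxels stay in the map support (stable denominators downstream)
    fm = FeatureMap("ADI", adi, mask, valid=stretches.valid & mask)
    fm.flags["clamped"] = clamped & mask
    return fm


def sri_map(stretches: StretchMap, mask: np.ndarray | None = None) -> FeatureMap:
    """Slab-rod index in [0, 1] with degenerate-case conventions.

    The λ2 = λ3 (rod) limit with λ1 > λ2 takes the limiting value 1; the
    fully isotropic case (numerator and denominator both zero) takes 0 by
    convention and is flagged isotropic.
    """
    lam = stretches.lambdas
    l1, l2, l3 = lam[..., 0], lam[..., 1], lam[..., 2]
    num = l3 * (l1 - l2)
    den = np.maximum(l2, EPS_CLAMP) * (l2 - l3)

    isotropic = (np.abs(num) <= _EPS_TIE) & (np.abs(den) <= _EPS_TIE)
    rod_limit = (den <= _EPS_TIE) & (num > _EPS_TIE)

    safe_den = np.where(den > _EPS_TIE, den, 1.0)
    sri = np.arctan(num / safe_den) / (np.pi / 2)
    sri = np.where(rod_limit, 1.0, sri)
    sri = np.where(isotropic, 0.0, sri)
    sri = np.clip(sri, 0.0, 1.0)

    if mask is None:
        mask = np.ones(sri.shape, dtype=bool)
    fm = FeatureMap("SRI", sri, mask, valid=stretches.valid & mask)
    fm.flags["isotropic"] = isotropic & mask
    return fm


def deformation_maps(
    T: DisplacementField,
    mask: np.ndarray | None = None,
    stretch_mode: str = "singular_values",
) -> dict[str, FeatureMap]:
    """All three deformation maps (Jacobian, ADI, SRI) restricted to mask."""
    stretches = stretches_from_field(T, stretch_mode)
    return {
        "Jacobian": jacobian_map(stretches, mask),
        "ADI": adi_map(stretches, mask),
        "SRI": sri_map(stretches, mask),
    }
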