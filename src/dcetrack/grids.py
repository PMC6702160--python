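"""Shared imaging data model: regular 3D grids, displacement fields, DCE studies.

All geometry is expressed in world millimeters with voxel centers at
``origin + index * spacing`` (0-based indices, axis-aligned grids).  Sampling
outside the grid extent clamps to the nearest edge value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
from scipy import ndimage


@dataclass
class VolumeGrid:
    """A 3D scalar image on a regular axis-aligned grid.

    Parameters
    ----------
    values : (nx, ny, nz) float array
        Voxel intensities, arbitrary units.
    spacing_mm : (3,) float array
        Per-axis voxel size in millimeters; strictly positive.
    origin_mm : (3,) float array
        World coordinates of the center of voxel (0, 0, 0).
    """

    values: np.ndarray
    spacing_mm: np.ndarray
    origin_mm: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("VolumeGrid expects a 3D array")
        self.spacing_mm = np.asarray(self.spacing_mm, dtype=float).reshape(3)
        if np.any(self.spacing_mm <= 0):
            raise ValueError("spacing_mm must be > 0 per axis")
        if self.origin_mm is None:
            self.origin_mm = np.zeros(3)
        self.origin_mm = np.asarray(self.origin_mm, dtype=float).reshape(3)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("VolumeGrid values must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))

    def like(self, values: np.ndarray) -> "VolumeGrid":
        """New volume with the same geometry and different values."""
        return VolumeGrid(np.asarray(values, dtype=float), self.spacing_mm.copy(),
                          self.origin_mm.copy())

    def copy(self) -> "VolumeGrid":
        return self.like(self.values.copy())

    def world_coordinates(self) -> np.ndarray:
        """(nx, ny, nz, 3) array of voxel-center world coordinates."""
        idx = np.indices(self.shape).astype(float)
        return np.stack(
            [self.origin_mm[a] + idx[a] * self.spacing_mm[a] for a in range(3)],
            axis=-1,
        )

    def world_to_index(self, pts_world: np.ndarray) -> np.ndarray:
        """Continuous voxel indices of world points (..., 3)."""
        pts = np.asarray(pts_world, dtype=float)
        return (pts - self.origin_mm) / self.spacing_mm

    def sample_world(self, pts_world: np.ndarray, interp: str = "linear") -> np.ndarray:
        """Sample the volume at world points; edge values outside the extent."""
        idx = self.world_to_index(pts_world)
        return sample_index(self.values, idx, interp)

    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[:3, :3] = np.diag(self.spacing_mm)
        aff[:3, 3] = self.origin_mm
        return aff

    def same_grid(self, other: "VolumeGrid") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing_mm, other.spacing_mm)
            and np.allclose(self.origin_mm, other.origin_mm)
        )


_INTERP_ORDER = {"linear": 1, "nearest": 0}


def sample_index(values: np.ndarray, idx: np.ndarray, interp: str = "linear") -> np.ndarray:
    """Sample an array at continuous voxel indices (..., 3), edge-clamped."""
    if interp not in _INTERP_ORDER:
        raise ValueError(f"unknown interp mode {interp!r}; use 'linear' or 'nearest'")
    idx = np.asarray(idx, dtype=float)
    coords = np.moveaxis(idx, -1, 0)
    return ndimage.map_coordinates(
        values, coords, order=_INTERP_ORDER[interp], mode="nearest"
    )


@dataclass
class DisplacementField:
    """Per-voxel displacement u(x) in mm on the fixed (pre-treatment) grid.

    The transform convention is T(x) = x + u(x): fixed-grid world coordinates
    are mapped into the moving (early-treatment) image's world frame.
    """

    u: np.ndarray  # (nx, ny, nz, 3), mm
    spacing_mm: np.ndarray
    origin_mm: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self):
        self.u = np.asarray(self.u, dtype=float)
        if self.u.ndim != 4 or self.u.shape[-1] != 3:
            raise ValueError("DisplacementField expects a (nx, ny, nz, 3) array")
        if not np.all(np.isfinite(self.u)):
            raise ValueError("displacement field must be finite")
        self.spacing_mm = np.asarray(self.spacing_mm, dtype=float).reshape(3)
        if self.origin_mm is None:
            self.origin_mm = np.zeros(3)
        self.origin_mm = np.asarray(self.origin_mm, dtype=float).reshape(3)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.u.shape[:3]  # type: ignore[return-value]

    @classmethod
    def identity(cls, like: VolumeGrid) -> "DisplacementField":
        return cls(np.zeros(like.shape + (3,)), like.spacing_mm.copy(),
                   like.origin_mm.copy())

    def grid(self) -> VolumeGrid:
        """The fixed grid geometry as an (empty) VolumeGrid."""
        return VolumeGrid(np.zeros(self.shape), self.spacing_mm, self.origin_mm)

    def mapped_points(self) -> np.ndarray:
        """T(x) = x + u(x) at every fixed-grid voxel center, world mm."""
        return self.grid().world_coordinates() + self.u


@dataclass
class DCEStudy:
    """One DCE-MRI visit: pre-contrast and two post-contrast volumes.

    All three volumes share one grid; times are minutes from injection with
    t0 < t1 < t2 (t0 is the pre-contrast acquisition).
    """

    vol_t0: VolumeGrid
    vol_t1: VolumeGrid
    vol_t2: VolumeGrid
    times_min: tuple[float, float, float] = (0.0, 2.5, 7.5)

    def __post_init__(self):
        t0, t1, t2 = self.times_min
        if not (t0 < t1 < t2):
            raise ValueError("acquisition times must be strictly increasing")
        if not (self.vol_t0.same_grid(self.vol_t1) and self.vol_t0.same_grid(self.vol_t2)):
            raise ValueError("DCE volumes must share one grid")

    @property
    def grid(self) -> VolumeGrid:
        return self.vol_t0

    def volumes(self) -> tuple[VolumeGrid, VolumeGrid, VolumeGrid]:
        return (self.vol_t0, self.vol_t1, self.vol_t2)


@dataclass
class StretchMap:
    """Principal stretches (λ1 ≥ λ2 ≥ λ3) of the transform at every voxel."""

    lambdas: np.ndarray  # (nx, ny, nz, 3), sorted descending
    valid: np.ndarray  # bool, False where the gradient was degenerate
    spacing_mm: np.ndarray = None  # type: ignore[assignment]
    origin_mm: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self):
        self.lambdas = np.asarray(self.lambdas, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.spacing_mm is None:
            self.spacing_mm = np.ones(3)
        if self.origin_mm is None:
            self.origin_mm = np.zeros(3)


@dataclass
class FeatureMap:
    """A per-voxel scalar feature restricted to a tumor mask (FTV1)."""

    name: str
    values: np.ndarray
    mask: np.ndarray
    valid: np.ndarray = None  # type: ignore[assignment]
    flags: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.valid is None:
            self.valid = self.mask.copy()
        self.valid = np.asarray(self.valid, dtype=bool) & self.mask

    def masked_values(self) -> np.ndarray:
        """Values at valid mask voxels, 1D."""
        return self.values[self.valid]


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------

def save_volume(vol: VolumeGrid, path) -> None:
    nib.save(nib.Nifti1Image(vol.values.astype(np.float32), vol.affine()), str(path))


def load_volume(path) -> VolumeGrid:
    img = nib.load(str(path))
    aff = img.affine
    spacing = np.abs(np.diag(aff)[:3])
    origin = aff[:3, 3].copy()
    return VolumeGrid(np.asarray(img.get_fdata(), dtype=float), spacing, origin)


def save_displacement(fieldu: DisplacementField, path) -> None:
    """4D NIfTI: 4th dimension holds the 3 displacement components in mm."""
    aff = np.eye(4)
    aff[:3, :3] = np.diag(fieldu.spacing_mm)
    aff[:3, 3] = fieldu.origin_mm
    nib.save(nib.Nifti1Image(fieldu.u.astype(np.float32), aff), str(path))


def load_displacement(path) -> DisplacementField:
    img = nib.load(str(path))
    aff = img.affine
    data = np.asarray(img.get_fdata(), dtype=float)
    if data.ndim != 4 or data.shape[-1] != 3:
        raise ValueError("displacement NIfTI must be 4D with 3 components")
    return DisplacementField(data, np.abs(np.diag(aff)[:3]), aff[:3, 3].copy())
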