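"""Per-tumor heterogeneity indices and the 7 + 5 feature vectors.

Each voxel-wise feature map over the pre-treatment tumor (FTV1) is collapsed
to a single index: the fraction of voxels that increased between visits for
the Jacobian (increase = expansion, J > 1) and the four kinetic PRMs
(increase = PRM > 0), and a histogram entropy for the anisotropy maps (ADI,
SRI).  The entropy is, as-printed convention, Σ P(i) log2 P(i) over
equal-width bins of the per-tumor observed range — a nonpositive number
minimized by the uniform histogram and 0 at a point mass; the conventional
(negated) Shannon form is available.  Together with the 5 aggregate
longitudinal features this yields the per-tumor feature vector the outcome
models consume.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grids import FeatureMap
from .phantom import AGGREGATE_FEATURES, VOXELWISE_FEATURES

#: Maps summarized by fraction-increased, with their thresholds.
FRACTION_MAPS = {
    "Jacobian": 1.0,  # expansion
    "PRM_PE": 0.0,
    "PRM_WIS": 0.0,
    "PRM_WOS": 0.0,
    "PRM_SER": 0.0,
}

#: Maps summarized by histogram entropy.
ENTROPY_MAPS = ("ADI", "SRI")

_FRAC_COLUMN = {
    "Jacobian": "frac_jacobian",
    "PRM_PE": "frac_PRM_PE",
    "PRM_WIS": "frac_PRM_WIS",
    "PRM_WOS": "frac_PRM_WOS",
    "PRM_SER": "frac_PRM_SER",
}


@dataclass
class TumorSummary:
    """The per-tumor feature vector: 7 voxel-wise + 5 aggregate values."""

    voxelwise: dict[str, float]
    aggregate: dict[str, float]
    ftv1_cm3: float
    ftv2_cm3: float
    n_valid: dict[str, int] = field(default_factory=dict)
    flags: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if tuple(self.voxelwise) != tuple(VOXELWISE_FEATURES):
            raise ValueError("voxelwise block must hold exactly the 7 indices in order")
        if tuple(self.aggregate) != tuple(AGGREGATE_FEATURES):
            raise ValueError("aggregate block must hold exactly the 5 features in order")

    def as_row(self) -> dict[str, float]:
        row = dict(self.voxelwise)
        row.update(self.aggregate)
        row["ftv1_cm3"] = self.ftv1_cm3
        row["ftv2_cm3"] = self.ftv2_cm3
        return row


def fraction_increased(fmap: FeatureMap, threshold: float = 0.0) -> float:
    """Fraction of valid voxels whose value strictly exceeds the threshold.

    Threshold 0 for PRM maps (an increased feature) and 1 for the Jacobian
    (expansion); ties count as not increased.  Raises if the map has no
    valid voxels.
    """
    vals = fmap.masked_values()
    if vals.size == 0:
        raise ValueError(f"fraction_increased: no valid voxels in map {fmap.name!r}")
    return float(np.mean(vals > threshold))


def entropy_index(fmap: FeatureMap, n_bins: int = 32, convention: str = "as_printed") -> float:
    """Histogram entropy of a feature map over its per-tumor observed range.

    Values are binned into ``n_bins`` equal-width bins spanning [min, max]
    of the valid voxels; P(i) are the bin proportions (empty bins contribute
    0).  ``as_printed`` returns Σ P log2 P (≤ 0); ``shannon`` returns the
    negated conventional form.  A constant map occupies a single bin and
    returns 0 under both conventions.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if convention not in ("as_printed", "shannon"):
        raise ValueError(f"unknown entropy convention {convention!r}")
    vals = fmap.masked_values()
    if vals.size == 0:
        raise ValueError(f"entropy_index: no valid voxels in map {fmap.name!r}")
    vmin, vmax = float(vals.min()), float(vals.max())
    if vmax - vmin < 1e-300:
        return 0.0
    counts, _ = np.histogram(vals, bins=n_bins, range=(vmin, vmax))
    p = counts[counts > 0] / vals.size
    h = float(np.sum(p * np.log2(p)))
    return h if convention == "as_printed" else -h


def summarize_tumor(
    maps: dict[str, FeatureMap],
    aggregates: dict[str, float],
    ftv1_cm3: float,
    ftv2_cm3: float,
    entropy_bins: int = 32,
    entropy_convention: str = "as_printed",
    prm_deadband: float = 0.0,
) -> TumorSummary:
    """Collapse the feature maps to the 7 voxel-wise indices and assemble
    the 5 aggregate features into one per-tumor summary.

    ``maps`` must contain Jacobian, ADI, SRI and the four PRM maps (all on
    FTV1); a missing map is a hard error naming it.  ``prm_deadband``
    optionally raises the PRM increase threshold above 0.
    """
    needed = list(FRACTION_MAPS) + list(ENTROPY_MAPS)
    for name in needed:
        if name not in maps:
            raise KeyError(f"summarize_tumor: missing feature map {name!r}")
    missing_agg = set(AGGREGATE_FEATURES) - set(aggregates)
    if missing_agg:
        raise KeyError(f"summarize_tumor: missing aggregate features {sorted(missing_agg)}")

    voxelwise: dict[str, float] = {}
    n_valid: dict[str, int] = {}
    flags: dict[str, str] = {}
    for name, thr in FRACTION_MAPS.items():
        if name != "Jacobian" and prm_deadband > 0:
            thr = prm_deadband
        fm = maps[name]
        voxelwise[_FRAC_COLUMN[name]] = fraction_increased(fm, thr)
        n_valid[name] = int(fm.valid.sum())
    for name in ENTROPY_MAPS:
        fm = maps[name]
        voxelwise[f"entropy_{name}"] = entropy_index(fm, entropy_bins, entropy_convention)
        n_valid[name] = int(fm.valid.sum())

    voxelwise = {k: voxelwise[k] for k in VOXELWISE_FEATURES}
    aggregate = {k: float(aggregates[k]) for k in AGGREGATE_FEATURES}
    for k, v in aggregate.items():
        if not np.isfinite(v):
            flags[k] = "undefined"
    return TumorSummary(voxelwise, aggregate, float(ftv1_cm3), float(ftv2_cm3),
                        n_valid, flags)
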