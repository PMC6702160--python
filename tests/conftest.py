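import numpy as np
import pytest
from scipy import ndimage

import dcetrack as dt


@pytest.fixture
def clean_spec():
    """Small noise-free, bias-free phantom spec with identity deformation."""
    return dt.PhantomSpec(grid_shape=(24, 24, 24), noise_sd=0.0, bias_amplitude=0.0)


@pytest.fixture
def textured_volume():
    """Smooth textured volume with gradient information everywhere."""

    def make(n=32, seed=0, spacing=1.0):
        rng = np.random.default_rng(seed)
        base = ndimage.gaussian_filter(rng.standard_normal((n, n, n)), 3.0, mode="nearest")
        base = 100 + 50 * base / np.abs(base).max()
        return dt.VolumeGrid(base, np.ones(3) * spacing)

    return make


@pytest.fixture
def uniform_stretch_field():
    """Displacement field of a uniform affine map with given principal stretches."""

    def make(stretches, n=12, spacing=1.0):
        grid = dt.VolumeGrid(np.zeros((n, n, n)), np.ones(3) * spacing)
        a = np.diag(stretches)
        pts = grid.world_coordinates()
        center = np.array(grid.shape) * spacing / 2
        u = (pts - center) @ a.T + center - pts
        return dt.DisplacementField(u, grid.spacing_mm, grid.origin_mm)

    return make


def constant_study(value=100.0, n=8, times=(0.0, 2.5, 7.5)):
    g = dt.VolumeGrid(np.full((n, n, n), float(value)), np.ones(3))
    return dt.DCEStudy(g, g.copy(), g.copy(), times_min=times)


@pytest.fixture
def make_curve_study():
    """Uniform study with a given three-point intensity curve."""

    def make(i0, i1, i2, n=4, times=(0.0, 2.5, 7.5)):
        g = dt.VolumeGrid(np.full((n, n, n), float(i0)), np.ones(3))
        return dt.DCEStudy(g, g.like(np.full((n, n, n), float(i1))),
                           g.like(np.full((n, n, n), float(i2))), times_min=times)

    return make
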