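"""Shared fixtures: small phantoms reused across test modules."""

import numpy as np
import pytest

from nci3d import phantom as ph
from nci3d.pipeline import RunConfig


@pytest.fixture(scope="session")
def single_bead():
    """One fully excluding 1.0 μm sphere in a clean bath (no optics yet)."""
    spec = ph.bead_grid_spec(1, 1.0, seed=3, object_attenuation=0.0)
    spec.poisson_gain = 0.0
    spec.gaussian_sd = 0.0
    stack, gt = ph.make_bead_phantom(spec)
    return spec, stack, gt


@pytest.fixture(scope="session")
def small_cell():
    """Noiseless cell phantom: 12 granules in a ~200 μm³ cell."""
    spec = ph.random_cell_spec(
        200.0, 12, seed=7, poisson_gain=0.0, gaussian_sd=0.0,
        marked_fraction=0.75,
    )
    stack, gt = ph.make_cell_phantom(spec)
    return spec, stack, gt


@pytest.fixture
def noiseless_config():
    """Pipeline config for sharp synthetic data (no restoration needed)."""
    return RunConfig(deconvolve=False, seed=0)


def radial_void_slice(c_level=1000.0, scale=0.3, n=101, pixel=0.04):
    """Rasterised analytic void profile I(r) = C·(1 − exp(−(r/scale)²))."""
    yy, xx = np.meshgrid(
        (np.arange(n) + 0.5) * pixel, (np.arange(n) + 0.5) * pixel,
        indexing="ij",
    )
    cy = cx = (n / 2) * pixel
    r = np.hypot(yy - cy, xx - cx)
    return c_level * (1.0 - np.exp(-((r / scale) ** 2))), (n // 2, n // 2)
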