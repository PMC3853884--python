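"""Shared fixtures: the standard phantom study conditions, built once."""

from __future__ import annotations

import numpy as np
import pytest

from cbctprior import correct_cbct, standard_fixture
from cbctprior.phantom import PhantomSpec, generate_phantom_ct
from cbctprior.volume_io import ImageGrid, IntensityUnit, VolumetricImage


@pytest.fixture(scope="session")
def fixture0():
    """Standard phantom + degradation + rigid offset at seed 0."""
    return standard_fixture(0)


@pytest.fixture(scope="session")
def phantom0():
    """Clean phantom CT and ground-truth masks at seed 0."""
    return generate_phantom_ct(PhantomSpec(seed=0))


@pytest.fixture(scope="session")
def corrected_aligned(fixture0):
    """Correction of the aligned degraded CBCT (no rigid offset)."""
    return correct_cbct(fixture0.ct, fixture0.cbct_aligned, None,
                        fov_mask=fixture0.fov_aligned)


def make_image(shape=(16, 16, 16), spacing=(1.0, 1.0, 1.0), value=-1000.0,
               unit=IntensityUnit.HU, origin=None):
    """Small constant test volume."""
    if origin is None:
        origin = tuple(-(n - 1) * s / 2.0 for n, s in zip(shape, spacing))
    grid = ImageGrid(shape=shape, spacing=spacing, origin=origin)
    return VolumetricImage(grid=grid, voxels=np.full(shape, value), unit=unit)
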