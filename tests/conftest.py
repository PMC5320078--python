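"""Shared fixtures: small, fast phantoms for unit tests.

The small grid uses a coarser pixel so the same millimetre anatomy fits; the
full-resolution reference suite lives in test_acceptance.py only.
"""
from __future__ import annotations

import numpy as np
import pytest

from ventriseg.phantom import PhantomSpec, generate_phantom

SMALL_GRID = dict(grid_shape=(160, 160, 8), pixel_mm=0.8, slice_mm=5.0)


def small_spec(**overrides) -> PhantomSpec:
    params = dict(SMALL_GRID)
    params.update(overrides)
    return PhantomSpec(**params)


@pytest.fixture(scope="session")
def clean_phantom():
    """Noise-free, blur-free, untilted phantom without lesions."""
    return generate_phantom(small_spec(noise_sd_hu=0.0, psf_sigma_px=0.0, seed=11))


@pytest.fixture(scope="session")
def noisy_phantom():
    """Default-noise tilted phantom without lesions."""
    return generate_phantom(small_spec(tilt_deg=7.0, shift_px=(4.0, -3.0), seed=12))


@pytest.fixture(scope="session")
def default_phantom():
    """Full-resolution tilted phantom: the 30-voxel light-curve size filter
    needs fissure segments at clinical pixel size, so pose-recovery tests run
    at the default grid."""
    spec = PhantomSpec(tilt_deg=10.0, shift_px=(6.0, -4.0), seed=5)
    return spec, generate_phantom(spec)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20170207)
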