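"""Shared fixtures: small phantom pairs and random smooth velocity fields."""

import numpy as np
import pytest

from mdreg.core import VelocityField
from mdreg.synthetic import PhantomSpec, WarpSpec, make_pair, make_phantom


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def phantom32():
    """A 32^3 phantom with labels (deterministic)."""
    return make_phantom(PhantomSpec(shape=(32, 32, 32), n_shells=3, seed=11))


@pytest.fixture(scope="session")
def pair32():
    """A 32^3 fixed/moving pair with known ground-truth warp."""
    ph = PhantomSpec(shape=(32, 32, 32), n_shells=4, seed=5)
    wp = WarpSpec(amplitude=3.0, smoothness_sigma=3.0, seed=5)
    return make_pair(ph, wp)


@pytest.fixture(scope="session")
def smooth_svf24():
    """A smooth velocity field on a 24^3 grid, |v| <= 2 voxels."""
    return VelocityField(
        _smooth_field(np.random.default_rng(7), (24, 24, 24), 2.0))


def _smooth_field(rng, shape, amplitude, sigma=4.0):
    from scipy.ndimage import gaussian_filter

    v = np.stack([gaussian_filter(rng.standard_normal(shape), sigma)
                  for _ in range(3)])
    v *= amplitude / np.abs(v).max()
    return v.astype(np.float32)


@pytest.fixture(scope="session")
def smooth_field_factory():
    return _smooth_field
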