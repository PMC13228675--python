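import numpy as np
import pytest

from stvseg.phantom import PhantomParams, generate_phantom


@pytest.fixture(scope="session")
def crescent_pair():
    """One deterministic crescent phantom (volume, label)."""
    return generate_phantom(PhantomParams(seed=7))


@pytest.fixture(scope="session")
def ellipsoid_pair():
    """One deterministic ellipsoid phantom with 2 mm isotropic semi-axes."""
    p = PhantomParams(target_kind="ellipsoid", semi_axes_mm=(2.0, 2.0, 2.0),
                      seed=11)
    return generate_phantom(p)


@pytest.fixture()
def disc_mask():
    """64x64 binary disc of radius 10 px centred at (32, 32)."""
    yy, xx = np.mgrid[:64, :64]
    return (((yy - 32) ** 2 + (xx - 32) ** 2) <= 100).astype(np.uint8)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
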