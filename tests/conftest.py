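import numpy as np
import pytest

from ossart import (
    build_base_matrix,
    crime_free_pair,
    default_geometry,
    make_shepp_logan,
)


@pytest.fixture(scope="session")
def sl64():
    return make_shepp_logan(64)


@pytest.fixture(scope="session")
def base64x64(sl64):
    return build_base_matrix(default_geometry(64, 360), 64)


@pytest.fixture(scope="session")
def pair64():
    """Noiseless crime-free phantom/sinogram pair: n=64, Q=180."""
    return crime_free_pair(64, 180)


@pytest.fixture(scope="session")
def pair16():
    """Tiny pair for fast structural tests: n=16, Q=40."""
    return crime_free_pair(16, 40)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
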