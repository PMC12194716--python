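import numpy as np
import pytest

from cassfcm.fixtures import FixtureSpec, make_blob_fixture, make_cube_fixture
from cassfcm.image import CIELAB, RasterImage


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_lab_image(rng, M, N):
    """A random but in-range CIELab image."""
    lab = np.empty((M, N, 3))
    lab[:, :, 0] = rng.uniform(5, 95, (M, N))
    lab[:, :, 1:] = rng.uniform(-60, 60, (M, N, 2))
    return RasterImage(lab, CIELAB)


@pytest.fixture
def lab8(rng):
    return random_lab_image(rng, 8, 8)


@pytest.fixture(scope="session")
def blob_fixture():
    """Default two-region deposit fixture (128x128, contrast 30)."""
    return make_blob_fixture(FixtureSpec("blob-deposit"))


@pytest.fixture(scope="session")
def cube_fixture():
    """Default five-region cube fixture (128x128)."""
    return make_cube_fixture(FixtureSpec("cube"))
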