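import numpy as np
import pytest

from ricstf.geometry import ScanGeometry, PSFModel


@pytest.fixture(scope="session")
def geometry_128():
    """Paper-style per-pixel/per-line timing on a 128 x 128 raster."""
    return ScanGeometry(n_rows=128, n_cols=128, frame_time_s=128 * 4.94e-3)


@pytest.fixture(scope="session")
def geometry_256():
    return ScanGeometry(n_rows=256, n_cols=256, frame_time_s=256 * 4.94e-3)


@pytest.fixture(scope="session")
def psf():
    return PSFModel()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
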