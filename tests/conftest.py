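import numpy as np
import pytest

from zoomsid.marker_reference import default_library


@pytest.fixture(scope="session")
def lib():
    return default_library()


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def gaussian_peaks(mz, centers, amps, sigma=0.08):
    """Sum of Gaussian profiles on an m/z grid."""
    y = np.zeros_like(mz)
    for c, a in zip(centers, amps):
        y += a * np.exp(-0.5 * ((mz - c) / sigma) ** 2)
    return y
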