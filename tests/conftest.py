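import numpy as np
import pytest

from ssdmix.ssd import SSDMixture, SSDParams, ssd_sample


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def skewed_params():
    """Parameter sets spanning b in {0.5, 1, 2} with skewed alpha and beta."""
    return [
        SSDParams([3.0, 1.5], [0.2, 0.8], 0.5),
        SSDParams([1.2, 4.0], [0.6, 0.4], 1.0),
        SSDParams([2.0, 2.0], [0.3, 0.7], 2.0),
        SSDParams([5.0, 0.8], [0.5, 0.5], 0.5),
        SSDParams([0.9, 2.5], [0.25, 0.75], 2.0),
    ]


@pytest.fixture(scope="session")
def skewed_params_3d():
    return [
        SSDParams([3.0, 1.5, 2.0], [0.2, 0.5, 0.3], 0.5),
        SSDParams([1.2, 4.0, 0.9], [0.4, 0.35, 0.25], 1.0),
        SSDParams([2.5, 1.1, 3.3], [0.3, 0.3, 0.4], 2.0),
    ]


@pytest.fixture(scope="session")
def two_component_mixture():
    return SSDMixture(
        [0.4, 0.6],
        (
            SSDParams([2.0, 3.0, 1.5], [0.2, 0.5, 0.3], 0.8),
            SSDParams([4.0, 1.0, 2.0], [0.4, 0.3, 0.3], 1.3),
        ),
    )


@pytest.fixture(scope="session")
def single_component_data():
    """5000 draws from the recovery target, used by several fitting tests."""
    theta = SSDParams([5.0, 2.0, 3.0], [0.3, 0.3, 0.4], 1.5)
    return theta, ssd_sample(theta, 5000, 0)
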