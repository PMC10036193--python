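import numpy as np
import pytest

from vertemtl import phantom


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_cfg():
    """Fast phantom config for unit tests (full-size geometry is exercised
    in the acceptance suite)."""
    return phantom.PhantomConfig(image_size=128, vertebra_axes_range=(14.0, 24.0))


@pytest.fixture(scope="session")
def small_case(small_cfg):
    return phantom.generate_case(small_cfg, np.random.default_rng(7), "fix_case")
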