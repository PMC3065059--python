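import numpy as np
import pytest

from calculoscope import PhantomConfig, generate_phantom


@pytest.fixture(scope="session")
def phantom():
    """Default phantom: 5 lumina, 3 interior calculi, seed 7."""
    return generate_phantom(PhantomConfig(seed=7))


@pytest.fixture(scope="session")
def phantom_no_calculi():
    return generate_phantom(PhantomConfig(seed=3, n_calculi=0))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
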