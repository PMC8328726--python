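import numpy as np
import pytest
from hypothesis import settings

import mritex as mx

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_cohort():
    """Balanced 20-sample phantom cohort shared by feature tests."""
    return mx.generate_cohort(10, mx.default_spec(), seed=42)


@pytest.fixture(scope="session")
def phantom():
    return mx.generate_phantom(mx.default_spec(seed=5))
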