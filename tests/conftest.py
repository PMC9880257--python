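import numpy as np
import pytest
from hypothesis import settings

from cionacpg.synthetic_data import KernelParams

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def kernel():
    """Default GCaMP6s-like read-out."""
    return KernelParams()


@pytest.fixture
def noiseless_kernel():
    """Deterministic read-out for exact-recovery tests."""
    return KernelParams(noise_sd=0.0, amplitude_cv=0.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20230113)
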