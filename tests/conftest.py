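import numpy as np
import pytest

from synaptoquant.quantal import QuantalParams


@pytest.fixture
def reference_model() -> QuantalParams:
    """A well-separated quantal model used across fitting tests."""
    return QuantalParams(q=0.6, sigma0=0.1, n=5, p=0.3)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
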