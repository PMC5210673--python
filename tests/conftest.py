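import numpy as np
import pytest

from synchrolang import build_k_regular


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_net():
    """Reference network: n=10, k=4 (the model's standard setting)."""
    return build_k_regular(10, 4, seed=7)
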