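import numpy as np
import pytest

from chanzyme import GatingScheme


@pytest.fixture(scope="session")
def nv_scheme() -> GatingScheme:
    """Wild-type-like gating rates: P_o ~ 0.5, ~1.5 s bursts, ~2 ms flickers."""
    return GatingScheme(k_so=0.67, k_os=0.67, k_of=2.68, k_fo=500.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
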