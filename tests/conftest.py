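import numpy as np
import pytest
from hypothesis import settings

from trareco.simulate import _random_seq

settings.register_profile("derandomized", derandomize=True, deadline=None)
settings.load_profile("derandomized")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def rand_seq(rng, n: int) -> str:
    return _random_seq(rng, n)
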