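import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_dna(rng, n, gc=0.46):
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    idx = np.searchsorted(np.cumsum(p), rng.random(n), side="right")
    return bases[np.minimum(idx, 3)].tobytes().decode()


@pytest.fixture
def make_dna(rng):
    return lambda n, gc=0.46: random_dna(rng, n, gc)
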