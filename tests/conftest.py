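import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20240501)


@pytest.fixture
def subject():
    from fftgait.core_io import SubjectProfile

    return SubjectProfile("test", 1.30, 0)


@pytest.fixture
def constant_walk():
    """Noiseless 30 s walk at 2.0 steps/s, 100 Hz, with ground truth."""
    from fftgait.core_io import SubjectProfile
    from fftgait.synthetic import GaitSimSpec, SimSegment, simulate_bout

    spec = GaitSimSpec(
        segments=(SimSegment("walk", 30.0, 2.0, 0.4, 0.12),), sample_rate=100.0, seed=11
    )
    return simulate_bout(spec, SubjectProfile("walker", 1.30, 0))
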