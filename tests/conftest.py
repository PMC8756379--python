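import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def flat_trajectory():
    from erkscope.trajectories import Trajectory

    times = np.arange(30, dtype=float)
    return Trajectory("flat", times, np.full(30, 1.5), smoothed=True)
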