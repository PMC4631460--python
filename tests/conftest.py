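import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cntsense import SensorParams

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def params() -> SensorParams:
    """The study sensor: kA=100 /(M s), kD=1e-3 /s, 10 sites, 1 s sampling."""
    return SensorParams(kA=100.0, kD=1e-3, NT=10, dt=1.0)


@pytest.fixture(scope="session")
def conc_grid() -> np.ndarray:
    return np.array([0.0, 1e-6, 1e-5, 1e-4])
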