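import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from qbetkit.simulate import CVSimParams, GridSpec


@pytest.fixture(scope="session")
def coarse_grid():
    """Fast explicit grid for tests that compare, not calibrate."""
    return GridSpec(n_time=6000)


@pytest.fixture(scope="session")
def coarse_cv_params(coarse_grid):
    def make(**overrides):
        overrides.setdefault("grid", coarse_grid)
        return CVSimParams(**overrides)

    return make


@pytest.fixture
def triangular_sweep():
    """A 1.2 V -> -0.2 V -> 1.2 V potential program with 301 samples."""
    down = np.linspace(1.2, -0.2, 151)
    up = np.linspace(-0.2, 1.2, 151)[1:]
    return np.concatenate([down, up])
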