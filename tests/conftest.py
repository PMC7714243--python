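import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import gaitar as g

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def noise_free_params() -> g.SimulationParams:
    """Generator settings with no AR fluctuation and no sensor noise."""
    return g.SimulationParams(fluctuation_sd=0.0, sensor_noise_sd=0.0)


@pytest.fixture(scope="session")
def sym_condition() -> g.GaitCondition:
    return g.GaitCondition("sym_1.00", 1.0, 1.0, 60.0)


@pytest.fixture(scope="session")
def noise_free_trial(sym_condition, noise_free_params):
    """One noise-free 60 s limb trial plus its ground-truth peak table."""
    return g.simulate_walking_trial(sym_condition, noise_free_params, "left", seed=42)


@pytest.fixture(scope="session")
def ar2_sample() -> np.ndarray:
    """A long AR(2) draw with known coefficients (0.5, 0.2)."""
    return g.simulate_ar2_series(0.5, 0.2, 100_000, 1.0, mean=0.0, seed=2024)
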