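import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import opvar as ov

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def logistic_38() -> ov.Signal:
    """x trajectory of the coupled logistic maps at (r, eps) = (3.8, 0.01)."""
    sx, _ = ov.simulate_coupled_logistic(ov.LogisticParams(r=3.8, eps=0.01))
    return sx


@pytest.fixture(scope="session")
def logistic_36() -> ov.Signal:
    """x trajectory of the coupled logistic maps at (r, eps) = (3.6, 0.01)."""
    sx, _ = ov.simulate_coupled_logistic(ov.LogisticParams(r=3.6, eps=0.01))
    return sx


@pytest.fixture(scope="session")
def henon_14() -> tuple:
    """(x, y) trajectories of the Henon map at (a, b) = (1.4, 0.3)."""
    return ov.simulate_henon(ov.HenonParams(a=1.4, b=0.3))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
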