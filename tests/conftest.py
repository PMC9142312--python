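import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from fractumor import (
    ModelParams,
    find_coexistence_equilibrium,
)

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

#: growth rates of the canonical study regime
STUDY_PARAMS = ModelParams(a=0.7455, b=0.7367, c=0.5619)
STUDY_IC = (0.4, 0.5, 0.5)


@pytest.fixture(scope="session")
def params() -> ModelParams:
    return STUDY_PARAMS


@pytest.fixture(scope="session")
def e4(params) -> np.ndarray:
    """Refined coexistence equilibrium for the canonical growth rates."""
    eq = find_coexistence_equilibrium(params)
    assert eq.converged
    return eq.coords
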