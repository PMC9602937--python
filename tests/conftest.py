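import hypothesis
import numpy as np
import pytest

from psychseir import (
    BASELINE_INITIAL_STATE,
    BASELINE_PARAMETERS,
    CompartmentState,
    ModelParameters,
)

hypothesis.settings.register_profile(
    "default", derandomize=True, max_examples=50, deadline=None
)
hypothesis.settings.load_profile("default")


@pytest.fixture
def baseline() -> ModelParameters:
    return BASELINE_PARAMETERS


@pytest.fixture
def all_susceptible() -> CompartmentState:
    return BASELINE_INITIAL_STATE


def random_params(rng: np.random.Generator, c_floor: float = 0.05,
                  f_floor: float = 0.01) -> ModelParameters:
    """Random valid parameter draw; c and f bounded away from zero so the
    analytic fixed point is well-defined."""
    return ModelParameters(
        a=rng.uniform(0.05, 1.0),
        b=rng.uniform(0.05, 1.0),
        c=rng.uniform(c_floor, 1.0),
        d=rng.uniform(0.0, 1.0),
        e=rng.uniform(0.0, 1.0),
        f=rng.uniform(f_floor, 1.0),
        r=rng.uniform(0.0, 1.0),
        delta=rng.uniform(0.0, 1.0),
        K=rng.uniform(1.0, 20.0),
    )


def random_state(rng: np.random.Generator) -> CompartmentState:
    raw = rng.dirichlet(np.ones(4))
    return CompartmentState.from_array(raw / raw.sum())
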