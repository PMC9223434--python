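import numpy as np
import pytest

from aucsens import OdeModel, SimulationConfig, make_linear_chain


@pytest.fixture
def linear_model():
    """Production-degradation oracle dx/dt = k - d*x, k=1, d=0.5, x(0)=0."""
    return make_linear_chain(k=1.0, d=0.5)


@pytest.fixture
def linear_config():
    return SimulationConfig(horizon_T=10.0, n_points=1000)


@pytest.fixture
def decay_model():
    """Pure exponential decay dx/dt = -d*x with x(0)=1; closed-form oracle.

    Includes a 'dummy' parameter absent from the RHS, for zero-influence
    checks.
    """

    def rhs(t, y, p, u):
        return [-p["d"] * y[0]]

    return OdeModel(
        name="decay",
        state_names=["x"],
        param_names=["d", "dummy"],
        nominal_params={"d": 1.0, "dummy": 1.0},
        rhs=rhs,
        initial_state=np.array([1.0]),
        output_variable="x",
    )
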