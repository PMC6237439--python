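import numpy as np
import pytest

from synthgut import ModelParameters, Strain, SystemState, simulate
from synthgut.fit import exclude_decline
from synthgut.synthetic import NoiseConfig, fixture_params, generate_study


@pytest.fixture(scope="session")
def params() -> ModelParameters:
    return fixture_params()


@pytest.fixture(scope="session")
def tri_state(params) -> SystemState:
    """Average tri-culture inoculum with short lags, no initial acetate."""
    from synthgut.simulate import Q0_from_lag

    return SystemState.initial(
        X={Strain.RI: 0.58, Strain.FP: 0.04, Strain.BH: 0.21},
        Q={
            Strain.RI: Q0_from_lag(0.33, params.mu[Strain.RI]),
            Strain.FP: Q0_from_lag(0.08, params.mu[Strain.FP]),
            Strain.BH: Q0_from_lag(0.1, params.mu[Strain.BH]),
        },
    )


@pytest.fixture(scope="session")
def tri_trajectory(params, tri_state):
    return simulate(params, tri_state, np.linspace(0.0, 48.0, 193))


@pytest.fixture(scope="session")
def clean_study(params):
    """Noise-free study: observations equal the model exactly."""
    study = generate_study(
        params,
        NoiseConfig(abundance_cv=0.0, metabolite_sd=0.0, decline_rate=0.0, seed=1),
    )
    return {eid: exclude_decline(e) for eid, e in study.items()}


@pytest.fixture(scope="session")
def noisy_study(params):
    study = generate_study(params, NoiseConfig(seed=7))
    return {eid: exclude_decline(e) for eid, e in study.items()}
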