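import numpy as np
import pytest

import dcflux as dc


@pytest.fixture(scope="session")
def canonical():
    return dc.canonical_parameters()


@pytest.fixture(scope="session")
def state12():
    """Photoconverted pool of 1000 cells, switched 12 h post-injection."""
    return dc.SkinPoolState(x0=1000.0, t_pc=12.0)


@pytest.fixture(scope="session")
def constant_params(canonical):
    """Canonical loss rates but a constant (saline-type) migration hazard."""
    return dc.RateParameters(
        mu0=canonical.mu0,
        alpha=0.0,
        m=0.0,
        tau=canonical.tau,
        delta_alum=canonical.delta_alum,
        delta_saline=canonical.delta_saline,
    )


@pytest.fixture(scope="session")
def noiseless_study(canonical):
    """A deterministic (cv = 0) dataset over every standard design."""
    return dc.simulate_dataset(
        dc.study_designs(), canonical, noise=dc.NoiseModel(cv=0.0), seed=0
    )


@pytest.fixture(scope="session")
def noisy_study(canonical):
    """One cv = 0.2 dataset over the standard designs."""
    return dc.simulate_dataset(
        dc.study_designs(), canonical, noise=dc.NoiseModel(cv=0.2), seed=42
    )


def riemann_dln(t, state, params, condition, dt=0.001, rule="mid"):
    """Brute-force Riemann-sum oracle for the dLN convolution integral."""
    condition = dc.Condition.coerce(condition)
    delta = params.delta(condition)
    b = max(state.t_pc, t - params.tau)
    n = max(1, int(np.ceil((b - state.t_pc) / dt)))
    h = (b - state.t_pc) / n
    offset = 0.5 if rule == "mid" else 0.0
    s = state.t_pc + h * (np.arange(n) + offset)
    x = dc.skin_timecourse(s, state, params, condition)
    mu = dc.migration_rate(s, params, condition)
    return float(np.sum(mu * x * np.exp(-delta * (t - s - params.tau))) * h)
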