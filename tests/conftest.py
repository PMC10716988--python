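import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import fontansim as fs
from fontansim.sweep import run_condition

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def params():
    return fs.default_params()


@pytest.fixture(scope="session")
def baseline(params):
    """Converged zero-delay baseline beat (fraction 0.5) and its metrics."""
    tr = fs.simulate_to_steady_state(params)
    return params, tr, fs.beat_metrics(tr, params)


@pytest.fixture(scope="session")
def shape_runs(params):
    """Steady-state runs at the qualitative-shape conditions (dT = 90 ms)."""
    out = {}
    for fraction in (0.10, 0.30, 0.70):
        cond, tr, st = run_condition(params, 90.0, fraction)
        out[fraction] = (cond, tr, st)
    return out


@pytest.fixture(scope="session")
def full_sweep(params):
    """The default 19 x 19 activation-delay by delayed-fraction sweep."""
    return fs.run_grid(params)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
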