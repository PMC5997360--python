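import numpy as np
import pytest

from circaclock.models import TissueModel, load_tissue_parameters, simulate_core_clock


@pytest.fixture(scope="session")
def all_tissues_model() -> TissueModel:
    return load_tissue_parameters("all_tissues")


@pytest.fixture(scope="session")
def liver_model() -> TissueModel:
    return load_tissue_parameters("liver")


@pytest.fixture(scope="session")
def core_trajectory(all_tissues_model):
    """Post-burn-in adaptive-engine trajectory used across modules."""
    return simulate_core_clock(all_tissues_model, duration=360.0, burn_in=240.0)


@pytest.fixture(scope="session")
def core_grid(all_tissues_model):
    """Fast-path uniform grid simulation (compiles numba once per session)."""
    from circaclock.fastsim import simulate_grid

    return simulate_grid(all_tissues_model.params, 360.0)


@pytest.fixture(scope="session")
def bundled_pwms():
    from circaclock.pwm import load_bundled_pwm

    return {name: load_bundled_pwm(name) for name in ("ebox", "rre", "dbox")}


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def constant_trajectory(values, t_span=(0.0, 400.0)):
    """A Trajectory that stays at `values` (zero rhs), for closed-form checks."""
    from circaclock.dde import HistoryFunction, integrate

    values = np.asarray(values, dtype=float)
    rhs = lambda t, y, d: np.zeros_like(y)
    return integrate(rhs, [], HistoryFunction(values), t_span, max_step=50.0)
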