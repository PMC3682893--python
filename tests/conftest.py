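import numpy as np
import pytest

from persisterfit import (
    FitConfig,
    InitialState,
    MechanisticParams,
    PlatingDesign,
    simulate_kill_curve,
)


@pytest.fixture
def design():
    return PlatingDesign()


@pytest.fixture
def mech():
    """Representative kill-curve rates: fast kill, slow two-way switching."""
    return MechanisticParams(m=2.0, a=0.01, b=0.05)


@pytest.fixture
def init():
    return InitialState(N0=1e7, fp=0.01)


@pytest.fixture
def curve(mech, init, design):
    return simulate_kill_curve(mech, init, design, seed=42)


@pytest.fixture
def fast_config():
    """Reduced multi-start config for tests that fit many curves."""
    return FitConfig(seed=0, n_starts=3, algorithms=("bfgs",))


def ode_oracle(mech, init, t_grid):
    """Adaptive numerical integration of the two-state system (RK45)."""
    from scipy.integrate import solve_ivp

    def rhs(t, y):
        n, p = y
        return [-(mech.m + mech.a) * n + mech.b * p, mech.a * n - mech.b * p]

    sol = solve_ivp(
        rhs, [0.0, float(np.max(t_grid))], [init.n0, init.p0],
        t_eval=np.atleast_1d(t_grid), method="LSODA", rtol=1e-11, atol=1e-290,
    )
    return sol.y[0], sol.y[1]
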