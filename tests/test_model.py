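"""Closed-form two-state model: eigenvalues, trajectories, identifiability."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from persisterfit import (
    FractionInterval,
    InitialState,
    MechanisticParams,
    ObservationalParams,
    eigenvalues,
    feasible_fp_interval,
    mech_to_obs,
    obs_to_mech,
    state_trajectory,
    total_cfu,
)
from persisterfit.model import DegenerateModelError, InfeasibleParametersError

from conftest import ode_oracle


def rate_draws(seed, n):
    """Log-uniform mechanistic parameter draws over the realistic ranges."""
    rng = np.random.default_rng(seed)

    def lu(lo, hi, size):
        return np.exp(rng.uniform(np.log(lo), np.log(hi), size))

    return zip(lu(0.1, 5, n), lu(1e-6, 0.1, n), lu(1e-6, 0.5, n), lu(1e-6, 0.2, n))


@pytest.mark.parametrize(
    "m,a,b,expected",
    [
        (2.0, 0.0, 0.0, (-2.0, 0.0)),      # persisters inert, normals die at m
        (0.0, 0.3, 0.7, (-1.0, 0.0)),      # pure switching conserves the total
        (2.0, 0.01, 0.05, (-2.0102550688468788, -0.04974493115312075)),  # root-finder oracle
    ],
)
def test_eigenvalues_examples(m, a, b, expected):
    lam1, lam2 = eigenvalues(MechanisticParams(m, a, b))
    assert lam1 == pytest.approx(expected[0], rel=1e-12, abs=1e-12)
    assert lam2 == pytest.approx(expected[1], rel=1e-12, abs=1e-12)


def test_eigenvalues_match_characteristic_polynomial():
    for m, a, b in [(1.3, 0.02, 0.2), (4.0, 0.07, 0.44), (0.6, 1e-5, 1e-4)]:
        lam1, lam2 = eigenvalues(MechanisticParams(m, a, b))
        roots = np.sort(np.roots([1.0, m + a + b, m * b]))
        assert lam1 == pytest.approx(roots[0], rel=1e-10)
        assert lam2 == pytest.approx(roots[1], rel=1e-10, abs=1e-12)


def test_negative_rates_rejected():
    with pytest.raises(ValueError):
        MechanisticParams(-1.0, 0.0, 0.0)
    with pytest.raises(ValueError):
        MechanisticParams(1.0, -0.1, 0.0)


def test_mech_to_obs_decoupled_limit():
    # a = b = 0: slow amplitude equals the persister count
    obs = mech_to_obs(MechanisticParams(2.0, 0.0, 0.0), InitialState(1e7, 0.01))
    assert obs.c1 == pytest.approx(9.9e6, rel=1e-12)
    assert obs.c2 == pytest.approx(1e5, rel=1e-12)
    assert (obs.lam1, obs.lam2) == (-2.0, 0.0)


def test_no_death_conserves_total():
    obs = mech_to_obs(MechanisticParams(0.0, 0.2, 0.4), InitialState(3e7, 0.05))
    tt = np.linspace(0, 48, 33)
    assert np.allclose(total_cfu(obs, tt), 3e7, rtol=1e-12)


def test_closed_form_matches_ode_oracle(mech, init):
    tt = np.linspace(0, 48, 25)
    obs = mech_to_obs(mech, init)
    n_ref, p_ref = ode_oracle(mech, init, tt)
    total = np.asarray(total_cfu(obs, tt))
    assert np.max(np.abs(total - (n_ref + p_ref)) / (n_ref + p_ref)) < 1e-8
    n, p = state_trajectory(mech, init, tt)
    assert np.max(np.abs(n - n_ref) / np.maximum(n_ref, 1e-12)) < 1e-8
    assert np.max(np.abs(p - p_ref) / np.maximum(p_ref, 1e-12)) < 1e-8


def test_closed_form_oracle_over_random_draws():
    tt = np.linspace(0, 48, 9)
    for m, a, b, fp in rate_draws(seed=7, n=25):
        mech = MechanisticParams(m, a, b)
        init = InitialState(1e7, fp)
        n_ref, p_ref = ode_oracle(mech, init, tt)
        total = np.asarray(total_cfu(mech_to_obs(mech, init), tt))
        assert np.max(np.abs(total - (n_ref + p_ref)) / (n_ref + p_ref)) < 1e-8


def test_total_cfu_examples():
    assert total_cfu(ObservationalParams(1e7, 0, -1.0, 0.0), 2.0) == pytest.approx(
        1e7 * math.exp(-2.0), rel=1e-12
    )
    obs = ObservationalParams(5e6, 5e3, -2.0, -0.01)
    assert total_cfu(obs, 0.0) == obs.c1 + obs.c2
    # frozen high-precision arithmetic oracle value
    assert total_cfu(obs, 24.0) == pytest.approx(3933.1393053327670, rel=1e-13)
    with pytest.raises(ValueError):
        total_cfu(obs, -1.0)


def test_trajectory_trivial_cases():
    # inert persisters: n -> 0, p stays at p0
    n, p = state_trajectory(MechanisticParams(2, 0, 0), InitialState(1e7, 0.01), 400.0)
    assert n == pytest.approx(0.0, abs=1e-6)
    assert p == pytest.approx(1e5, rel=1e-12)
    # no persisters ever formed
    n, p = state_trajectory(
        MechanisticParams(1.5, 0, 0), InitialState(1e6, 0.0), np.linspace(0, 48, 10)
    )
    assert np.all(p == 0)


def test_total_cfu_nonincreasing():
    tt = np.linspace(0, 48, 400)
    for m, a, b, fp in rate_draws(seed=11, n=20):
        vals = np.asarray(total_cfu(mech_to_obs(MechanisticParams(m, a, b), InitialState(1e7, fp)), tt))
        assert np.all(np.diff(vals) <= 1e-9 * vals[:-1])


def test_repeated_eigenvalue_boundary():
    # m = b, a = 0 collapses the discriminant to zero
    mech = MechanisticParams(1.0, 0.0, 1.0)
    assert eigenvalues(mech) == pytest.approx((-1.0, -1.0))
    with pytest.raises(DegenerateModelError):
        mech_to_obs(mech, InitialState(1e6, 0.1))
    # trajectory evaluation falls back to the (c1 + c2 t) e^{lam t} form
    init = InitialState(1e6, 0.1)
    tt = np.linspace(0, 10, 21)
    n, p = state_trajectory(mech, init, tt)
    n_ref, p_ref = ode_oracle(mech, init, tt)
    assert np.max(np.abs(n + p - n_ref - p_ref) / (n_ref + p_ref)) < 1e-8


def test_feasible_interval_boundary_case():
    # a = 0 puts the generating fp on the interval's upper endpoint
    obs = mech_to_obs(MechanisticParams(2, 0, 0), InitialState(1e7, 0.01))
    iv = feasible_fp_interval(obs)
    assert iv.fp_max == pytest.approx(0.01, rel=1e-9)
    assert iv.fp_min == 0.0


def grid_search_feasible_fp(obs, n_grid=20001):
    """Brute-force oracle: scan fp and test the inverse map for nonnegativity."""
    D = -(obs.c1 * obs.lam1 + obs.c2 * obs.lam2) / (obs.c1 + obs.c2)
    fps = np.linspace(0.0, 1.0 - 1e-9, n_grid)
    ok = []
    for fp in fps:
        u = 1.0 - fp
        m = D / u
        b = obs.lam1 * obs.lam2 / m
        a = -(obs.lam1 + obs.lam2) - m - b
        if m >= -1e-12 and b >= -1e-12 and a >= -1e-9:
            ok.append(fp)
    return (min(ok), max(ok)) if ok else None


def test_feasible_interval_matches_grid_search(mech, init):
    obs = mech_to_obs(mech, init)
    iv = feasible_fp_interval(obs)
    lo, hi = grid_search_feasible_fp(obs)
    assert iv.fp_min == pytest.approx(lo, abs=1e-4)
    assert iv.fp_max == pytest.approx(hi, abs=1e-4)
    # derived endpoint value for these rates
    assert iv.fp_max == pytest.approx(0.0151, abs=2e-4)
    assert iv.contains(init.fp)


@settings(derandomize=True, max_examples=60, deadline=None)
@given(
    m=st.floats(0.1, 5.0),
    a=st.floats(1e-6, 0.1),
    b=st.floats(1e-6, 0.5),
    fp=st.floats(1e-6, 0.2),
)
def test_interval_contains_generating_fraction(m, a, b, fp):
    obs = mech_to_obs(MechanisticParams(m, a, b), InitialState(1e7, fp))
    iv = feasible_fp_interval(obs)
    assert 0.0 <= iv.fp_min <= iv.fp_mid <= iv.fp_max < 1.0
    assert iv.fp_mid == pytest.approx((iv.fp_min + iv.fp_max) / 2)
    assert iv.contains(fp, atol=1e-9)


@settings(derandomize=True, max_examples=60, deadline=None)
@given(
    m=st.floats(0.1, 5.0),
    a=st.floats(1e-6, 0.1),
    b=st.floats(1e-6, 0.5),
    fp=st.floats(1e-6, 0.2),
)
def test_inverse_map_is_identity_at_true_fraction(m, a, b, fp):
    mech = MechanisticParams(m, a, b)
    obs = mech_to_obs(mech, InitialState(1e7, fp))
    back = obs_to_mech(obs, fp)
    assert back.m == pytest.approx(m, rel=1e-6)
    assert back.a == pytest.approx(a, rel=1e-6, abs=1e-9)
    assert back.b == pytest.approx(b, rel=1e-6, abs=1e-9)


def test_obs_to_mech_roundtrip_reproduces_obs(mech, init):
    obs = mech_to_obs(mech, init)
    back = obs_to_mech(obs, init.fp)
    obs2 = mech_to_obs(back, InitialState(obs.N0, init.fp))
    for attr in ("c1", "c2", "lam1", "lam2"):
        assert getattr(obs2, attr) == pytest.approx(getattr(obs, attr), rel=1e-9)


def test_obs_to_mech_zero_slow_eigenvalue_forces_b_zero():
    obs = mech_to_obs(MechanisticParams(2, 0.01, 0.0), InitialState(1e7, 0.01))
    assert obs.lam2 == 0.0
    iv = feasible_fp_interval(obs)
    assert obs_to_mech(obs, iv.fp_max).b == 0.0


def test_obs_to_mech_rejects_infeasible_fraction(mech, init):
    obs = mech_to_obs(mech, init)
    iv = feasible_fp_interval(obs)
    with pytest.raises(InfeasibleParametersError, match="feasible"):
        obs_to_mech(obs, iv.fp_max + 0.05)


def test_fraction_interval_invariants_enforced():
    with pytest.raises(ValueError):
        FractionInterval(0.2, 0.1, 0.3)
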