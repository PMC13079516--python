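"""Scalar gain quantities and the damped restoring dynamics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cdt import (
    ChallengeProtocol,
    DeviationState,
    DynamicsParams,
    TimeGrid,
    absolute_deviation,
    damping_regime,
    gain_dynamics,
    integrate_deviation,
    precision,
    precision_regularized,
    relative_deviation,
    solve_deviation_closed_form,
    subjective_interval,
    subjective_period,
)
from cdt.core import restoration_time

# (a, b) pairs spanning under-, critically and over-damped regimes
REGIME_PAIRS = [
    (1.0, 2.0), (0.25, 1.0), (9.0, 6.0),      # critical (b^2 = 4a)
    (0.75, 2.0), (1.0, 3.0), (0.5, 2.0),      # overdamped
    (4.0, 2.0), (2.0, 1.0), (9.0, 1.0),       # underdamped
]


@pytest.mark.parametrize(
    "fn,args,expected",
    [
        (subjective_interval, (1.0, 2.0), 2.0),
        (subjective_interval, (1.5, 2.0), 3.0),
        (subjective_interval, (0.5, 2.0), 1.0),
        (subjective_period, (1.0, 0.1), 0.1),
        (subjective_period, (1.2, 0.1), 0.12),
        (subjective_period, (0.8, 0.1), 0.08),
        (absolute_deviation, (0.12, 0.1), 0.02),
        (absolute_deviation, (0.1, 0.1), 0.0),
        (absolute_deviation, (0.08, 0.1), -0.02),
        (relative_deviation, (1.0,), 0.0),
        (relative_deviation, (1.2,), 0.2),
        (relative_deviation, (0.7,), -0.3),
        (precision, (0.2,), 5.0),
        (precision, (-0.5,), 2.0),
    ],
)
def test_scalar_quantities(fn, args, expected):
    assert fn(*args) == pytest.approx(expected)


def test_precision_diverges_at_perfect_timing():
    assert precision(0.0) == np.inf
    assert precision_regularized(0.0) == pytest.approx(1e6)
    assert precision_regularized(0.5) == pytest.approx(2.0)


@pytest.mark.parametrize(
    "bad_call",
    [
        lambda: subjective_interval(-1.0, 2.0),
        lambda: subjective_interval(1.0, -2.0),
        lambda: subjective_period(0.0, 0.1),
        lambda: relative_deviation(0.0),
        lambda: absolute_deviation(-0.1, 0.1),
        lambda: DynamicsParams(a=-1.0, b=2.0),
        lambda: DynamicsParams(a=1.0, b=0.0),
        lambda: DeviationState(d_r=-1.5),
        lambda: TimeGrid([0.0, 0.0, 1.0]),
        lambda: TimeGrid([-1.0, 1.0]),
        lambda: ChallengeProtocol(onset=-1, duration=1, amplitude=0.1),
    ],
)
def test_domain_errors(bad_call):
    with pytest.raises((ValueError, TypeError)):
        bad_call()


def test_damping_regime_labels():
    assert damping_regime(DynamicsParams(1.0, 2.0)) == "critical"
    assert damping_regime(DynamicsParams(0.75, 2.0)) == "overdamped"
    with pytest.warns(RuntimeWarning, match="underdamped"):
        assert damping_regime(DynamicsParams(4.0, 2.0)) == "underdamped"


def test_closed_form_critical_branch():
    # a=1, b=2, D(0)=1, D'(0)=0: D(t) = (1+t) e^{-t}
    grid = TimeGrid(np.linspace(0, 10, 101))
    traj = solve_deviation_closed_form(
        DynamicsParams(1.0, 2.0), DeviationState(1.0, 0.0), grid
    )
    assert traj.d_r[10] == pytest.approx(2 * np.exp(-1), abs=1e-12)
    np.testing.assert_allclose(traj.d_r, (1 + grid.t) * np.exp(-grid.t), atol=1e-12)


def test_closed_form_overdamped_branch():
    # a=0.75, b=2: roots -0.5, -1.5 -> D(t) = 1.5 e^{-t/2} - 0.5 e^{-3t/2}
    grid = TimeGrid(np.linspace(0, 10, 101))
    traj = solve_deviation_closed_form(
        DynamicsParams(0.75, 2.0), DeviationState(1.0, 0.0), grid
    )
    expected = 1.5 * np.exp(-0.5 * grid.t) - 0.5 * np.exp(-1.5 * grid.t)
    np.testing.assert_allclose(traj.d_r, expected, atol=1e-12)


def test_equilibrium_is_fixed_point():
    grid = TimeGrid(np.linspace(0, 5, 51))
    for a, b in [(1.0, 2.0), (4.0, 2.0), (0.75, 2.0)]:
        traj = solve_deviation_closed_form(
            DynamicsParams(a, b), DeviationState(0.0, 0.0), grid
        )
        assert np.all(traj.d_r == 0)
        num = integrate_deviation(DynamicsParams(a, b), DeviationState(0.0, 0.0), grid)
        assert np.all(num.d_r == 0)


@pytest.mark.parametrize("a,b", REGIME_PAIRS)
def test_integrator_matches_closed_form(a, b):
    """RK4 vs analytic solution: max abs error below 1e-8 on [0, 10]."""
    grid = TimeGrid(np.linspace(0, 10, 401))
    params = DynamicsParams(a, b)
    state = DeviationState(1.0, 0.3)
    exact = solve_deviation_closed_form(params, state, grid)
    numeric = integrate_deviation(params, state, grid)
    assert np.max(np.abs(numeric.d_r - exact.d_r)) < 1e-8


def test_integrator_matches_scipy_oracle():
    """Independent cross-check against a high-accuracy adaptive integrator."""
    from scipy.integrate import solve_ivp

    params = DynamicsParams(0.75, 2.0)
    state = DeviationState(1.0, -0.2)
    grid = TimeGrid(np.linspace(0, 10, 101))
    ours = integrate_deviation(params, state, grid)
    ref = solve_ivp(
        lambda t, y: [y[1], -params.a * y[0] - params.b * y[1]],
        (0, 10), [state.d_r, state.dd_r], t_eval=grid.t,
        rtol=1e-12, atol=1e-12, method="DOP853",
    )
    np.testing.assert_allclose(ours.d_r, ref.y[0], atol=1e-9)


@pytest.mark.parametrize("a,b", REGIME_PAIRS)
def test_asymptotic_restoration(a, b):
    """|D_r| decays below 1e-3 of its initial value for T from the slowest mode."""
    params = DynamicsParams(a, b)
    T = restoration_time(params, ratio=1e-3)
    grid = TimeGrid(np.array([0.0, T]))
    traj = solve_deviation_closed_form(params, DeviationState(0.5, 0.0), grid)
    assert abs(traj.d_r[-1]) < 1e-3 * 0.5


@pytest.mark.parametrize("a,b", [(1.0, 2.0), (0.75, 2.0), (0.25, 1.0), (1.0, 3.0)])
def test_non_oscillation_when_sufficiently_damped(a, b):
    """With b^2 >= 4a and zero initial velocity the solution never changes sign."""
    grid = TimeGrid(np.linspace(0, 30, 3001))
    traj = solve_deviation_closed_form(
        DynamicsParams(a, b), DeviationState(1.0, 0.0), grid
    )
    assert np.all(traj.d_r >= 0)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(
    a=st.floats(0.1, 10.0),
    b=st.floats(0.1, 10.0),
    kappa0=st.floats(0.1, 3.0),
)
def test_gain_deviation_change_of_variable(a, b, kappa0):
    """gain trajectory == 1 + deviation trajectory, exactly."""
    grid = TimeGrid(np.linspace(0, 5, 26))
    params = DynamicsParams(a, b)
    kap = gain_dynamics(params, kappa0, 0.0, grid)
    dev = solve_deviation_closed_form(params, DeviationState(kappa0 - 1.0, 0.0), grid)
    np.testing.assert_allclose(kap.kappa, 1.0 + dev.d_r, atol=1e-12, rtol=0)


def test_gain_dynamics_identity_at_unity():
    grid = TimeGrid(np.linspace(0, 10, 101))
    traj = gain_dynamics(DynamicsParams(1.0, 2.0), 1.0, 0.0, grid)
    assert np.all(traj.kappa == 1.0)


def test_challenge_then_release_two_phase_shape():
    """Step challenge: deviation rises during the epoch, then decays
    monotonically (overdamped) to near zero — the two-phase trajectory."""
    grid = TimeGrid.regular(30.0, 0.05)
    challenge = ChallengeProtocol(onset=1.0, duration=4.0, amplitude=0.5, shape="step")
    traj = integrate_deviation(
        DynamicsParams(0.75, 2.0), DeviationState(0.0, 0.0), grid, forcing=challenge
    )
    t = grid.t
    during = traj.d_r[(t >= 1.0) & (t <= 5.0)]
    assert np.all(np.diff(during) >= -1e-12)  # rising phase
    assert during.max() > 0.2
    after_settle = traj.d_r[t >= 7.0]
    assert np.all(np.diff(after_settle) <= 1e-12)  # smooth monotone decay
    assert abs(traj.d_r[-1]) < 1e-3


def test_impulse_challenge_kicks_velocity():
    grid = TimeGrid.regular(10.0, 0.01)
    challenge = ChallengeProtocol(onset=1.0, duration=0.0, amplitude=0.5,
                                  shape="impulse")
    traj = integrate_deviation(
        DynamicsParams(1.0, 2.0), DeviationState(0.0, 0.0), grid, forcing=challenge
    )
    assert np.all(traj.d_r[grid.t <= 1.0] == 0)
    assert traj.d_r[grid.t > 1.1].max() > 0.05


def test_trajectory_frame_and_summary():
    grid = TimeGrid(np.linspace(0, 1, 11))
    traj = gain_dynamics(DynamicsParams(1.0, 2.0), 1.0, 0.0, grid)
    df = traj.to_frame()
    assert list(df.columns) == ["t", "d_r", "kappa", "precision"]
    assert np.all(np.isinf(df["precision"]))
    assert traj.summary()["mean_kappa"] == pytest.approx(1.0)


def test_kappa_positivity_warning_on_crossing():
    from cdt.core import GainTrajectory

    grid = TimeGrid(np.array([0.0, 1.0]))
    with pytest.warns(RuntimeWarning, match="kappa"):
        GainTrajectory(grid=grid, d_r=np.array([0.0, -1.5]))
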