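"""Timescale weights, comparator contract and the two composition forms."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cdt import (
    ComparatorSpec,
    ComponentGains,
    DynamicsParams,
    DeviationState,
    TimeGrid,
    WeightProfile,
    combined_background_gain,
    comparator_correction,
    compose_trajectory,
    crossover_duration,
    gain_dynamics,
    register_comparator,
    total_gain_loglinear,
    total_gain_multiplicative,
    weights_at,
)

TAU_GRID = np.geomspace(0.01, 100.0, 200)


def test_weights_normalized_on_log_grid():
    w_cbl, w_bg, w_ctx = weights_at(TAU_GRID)
    total = w_cbl + w_bg + w_ctx
    np.testing.assert_allclose(total, 1.0, atol=1e-12, rtol=0)
    for w in (w_cbl, w_bg, w_ctx):
        assert np.all((w >= 0) & (w <= 1))


def test_weight_monotonicity_and_unimodality():
    w_cbl, w_bg, w_ctx = weights_at(TAU_GRID)
    assert np.all(np.diff(w_cbl) < 0), "cerebellar weight must fall with tau"
    assert np.all(np.diff(w_bg) > 0), "basal-ganglia weight must rise with tau"
    # cortical bump: interior argmax, rises before and falls after (the
    # symmetric log grid can tie two adjacent samples at the very top)
    i = int(np.argmax(w_ctx))
    assert 0 < i < TAU_GRID.size - 1
    assert np.all(np.diff(w_ctx[: i + 1]) > 0)
    assert np.all(np.diff(w_ctx[i:]) <= 0)
    assert np.all(np.diff(w_ctx[i + 1:]) < 0)


def test_crossover_at_one_second_default():
    w_cbl, w_bg, _ = weights_at(1.0)
    assert w_cbl == pytest.approx(w_bg, abs=1e-12)
    assert crossover_duration() == pytest.approx(1.0, abs=1e-5)


def test_sub_vs_supra_second_dominance():
    w_cbl_s, w_bg_s, _ = weights_at(0.05)
    w_cbl_l, w_bg_l, _ = weights_at(20.0)
    assert w_cbl_s > w_bg_s
    assert w_bg_l > w_cbl_l


def test_crossover_follows_profile():
    profile = WeightProfile(tau_cross=0.5)
    assert crossover_duration(profile) == pytest.approx(0.5, rel=1e-4)


def test_weight_domain_error():
    with pytest.raises(ValueError):
        weights_at(0.0)
    with pytest.raises(ValueError):
        weights_at(-1.0)


def test_combined_background_gain_values():
    w = (0.0, 0.5, 0.5)
    assert combined_background_gain(ComponentGains(1, 1, 1), w) == pytest.approx(1.0)
    assert combined_background_gain(
        ComponentGains(1, 2.0, 1.0), (0.5, 0.5, 0.0)
    ) == pytest.approx(np.sqrt(2), abs=1e-12)
    # exact cancellation of reciprocal gains at equal weights
    assert combined_background_gain(
        ComponentGains(1, 2.0, 0.5), (0.0, 0.5, 0.5)
    ) == pytest.approx(1.0, abs=1e-12)


def test_comparator_identity_contract():
    for g in (0.0, 0.3, 1.0):
        spec = ComparatorSpec(g=g)
        assert comparator_correction(1.0, 1.0, spec, (0.3, 0.4, 0.3)) == 1.0


def test_comparator_full_and_zero_correction():
    w = (0.0, 1.0, 0.0)
    gains = ComponentGains(kappa_cbl=1.0, kappa_bg=1.5, kappa_ctx=1.0)
    assert total_gain_multiplicative(gains, w, ComparatorSpec(g=1.0)) == pytest.approx(
        1.0, abs=1e-12
    )
    assert total_gain_multiplicative(gains, w, ComparatorSpec(g=0.0)) == pytest.approx(
        1.5, abs=1e-12
    )


def test_comparator_monotone_in_g():
    """With kappa_cbl = 1, |ln total| is non-increasing in comparator gain."""
    w = weights_at(2.0)
    gains = ComponentGains(kappa_cbl=1.0, kappa_bg=1.4, kappa_ctx=1.2)
    lnk = [
        abs(total_gain_loglinear(gains, w, ComparatorSpec(g=g)))
        for g in (0.0, 0.25, 0.5, 0.75, 1.0)
    ]
    assert all(b <= a + 1e-15 for a, b in zip(lnk, lnk[1:]))


def test_unknown_comparator_form_rejected():
    with pytest.raises(KeyError):
        ComparatorSpec(g=0.5, form="no_such_form")
    with pytest.raises(ValueError):
        ComparatorSpec(g=1.5)


def test_registered_comparator_is_usable():
    @register_comparator("_test_passthrough")
    def _passthrough(kc, kb, g, w):
        return 1.0

    spec = ComparatorSpec(g=0.5, form="_test_passthrough")
    gains = ComponentGains(1.0, 2.0, 1.0)
    w = (0.2, 0.5, 0.3)
    assert total_gain_multiplicative(gains, w, spec) == pytest.approx(2.0 ** 0.5)


def test_all_unity_gains_give_unity():
    gains = ComponentGains(1.0, 1.0, 1.0)
    for tau in (0.05, 1.0, 20.0):
        w = weights_at(tau)
        assert total_gain_multiplicative(gains, w) == pytest.approx(1.0, abs=1e-15)
        assert total_gain_loglinear(gains, w) == pytest.approx(0.0, abs=1e-15)


def test_loglinear_example():
    w = (0.0, 1.0, 0.0)
    gains = ComponentGains(kappa_cbl=1.0, kappa_bg=np.e, kappa_ctx=1.0)
    assert total_gain_loglinear(gains, w, ComparatorSpec(g=0.0)) == pytest.approx(1.0)


def test_multiplicative_loglinear_equivalence_random_draws():
    """exp(log-linear) == multiplicative over 1000 seeded random draws."""
    rng = np.random.default_rng(2024)
    for _ in range(1000):
        gains = ComponentGains(*np.exp(rng.normal(0, 0.3, 3)))
        tau = float(rng.uniform(0.05, 50.0))
        g = float(rng.uniform(0, 1))
        w = weights_at(tau)
        spec = ComparatorSpec(g=g)
        mult = total_gain_multiplicative(gains, w, spec)
        logl = total_gain_loglinear(gains, w, spec)
        assert abs(np.exp(logl) - mult) <= 1e-12 * max(1.0, mult)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    kb=st.floats(0.5, 2.0), kc=st.floats(0.5, 2.0), kcbl=st.floats(0.5, 2.0),
    tau=st.floats(0.05, 50.0), g=st.floats(0.0, 1.0),
)
def test_composition_equivalence_property(kb, kc, kcbl, tau, g):
    gains = ComponentGains(kappa_cbl=kcbl, kappa_bg=kb, kappa_ctx=kc)
    w = weights_at(tau)
    spec = ComparatorSpec(g=g)
    assert np.exp(total_gain_loglinear(gains, w, spec)) == pytest.approx(
        total_gain_multiplicative(gains, w, spec), rel=1e-12
    )


def test_compose_trajectory_matches_scalar_op():
    grid = TimeGrid(np.linspace(0, 5, 21))
    params = DynamicsParams(1.0, 2.0)
    cbl = gain_dynamics(params, 1.0, 0.0, grid)
    bg = gain_dynamics(params, 1.3, 0.0, grid)
    ctx = gain_dynamics(params, 0.9, 0.0, grid)
    spec = ComparatorSpec(g=0.4)
    out = compose_trajectory(cbl, bg, ctx, tau=2.0, spec=spec)
    w = weights_at(2.0)
    expected = [
        total_gain_multiplicative(ComponentGains(a, b, c), w, spec)
        for a, b, c in zip(cbl.kappa, bg.kappa, ctx.kappa)
    ]
    np.testing.assert_allclose(out.kappa, expected, rtol=1e-12)


def test_compose_trajectory_identity_and_grid_mismatch():
    grid = TimeGrid(np.linspace(0, 5, 21))
    ones = gain_dynamics(DynamicsParams(1, 2), 1.0, 0.0, grid)
    out = compose_trajectory(ones, ones, ones, tau=1.0)
    assert np.all(out.kappa == 1.0)
    other = gain_dynamics(DynamicsParams(1, 2), 1.0, 0.0,
                          TimeGrid(np.linspace(0, 5, 11)))
    with pytest.raises(ValueError, match="grid"):
        compose_trajectory(ones, ones, other, tau=1.0)


def test_comparator_ramp_pulls_gain_to_unity():
    """Constant kappa_bg = 1.5 with g ramping 0 -> 1 maps total gain
    monotonically from 1.5 down to 1 (kappa_cbl = 1, w_bg = 1)."""
    w = (0.0, 1.0, 0.0)
    gains = ComponentGains(1.0, 1.5, 1.0)
    ks = [total_gain_multiplicative(gains, w, ComparatorSpec(g=g))
          for g in np.linspace(0, 1, 11)]
    assert ks[0] == pytest.approx(1.5)
    assert ks[-1] == pytest.approx(1.0)
    assert all(b < a for a, b in zip(ks, ks[1:]))
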