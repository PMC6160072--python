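"""Unit and property tests for the stock-flow model core."""

import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import rumidyn as rd
from rumidyn.model import _ou_coeffs

GIRL_U = 4.97 / 6.0


# ---------------------------------------------------------------------------
# rate equations


def test_indicated_rumination_constant_terms(params):
    # at the origin only the constant (plus the gender shift) remains
    assert rd.indicated_rumination(0, 0, 0, 0, 0, params) == pytest.approx(params.theta1)
    assert rd.indicated_rumination(0, 0, 0, 1, 0, params) == pytest.approx(
        params.theta1 + params.theta3)


def test_indicated_rumination_fixed_point_self_consistency(params):
    # at the analytic fixed point the indicated value reproduces the stock
    ss = rd.steady_state(params, G=1, u=GIRL_U)
    ind = rd.indicated_rumination(ss.D, ss.R, ss.S, 1, 0.0, params)
    assert ind == pytest.approx(ss.R, abs=1e-9)


def test_indicated_depression_examples(params):
    assert rd.indicated_depression(0, 0, 0, params) == pytest.approx(params.theta6)
    # closed-form fixed point D* = (theta6 + theta7*R)/(1 - theta8) at R = 11.59
    R = 11.59
    D_star = (params.theta6 + params.theta7 * R) / (1 - params.theta8)
    assert rd.indicated_depression(D_star, R, 0, params) == pytest.approx(D_star, abs=1e-3)
    p0 = params.with_theta(theta7=0.0, theta8=0.0)
    assert rd.indicated_depression(123.0, 45.0, 0, p0) == pytest.approx(params.theta6)


def test_indicated_values_reject_non_finite(params):
    with pytest.raises(ValueError):
        rd.indicated_rumination(np.nan, 0, 0, 0, 0, params)
    with pytest.raises(ValueError):
        rd.indicated_depression(0, np.inf, 0, params)


def test_memory_time_slope_and_floor(params):
    assert rd.memory_time(1.0, params) == pytest.approx(params.theta9)
    assert rd.memory_time(10.0, params) == pytest.approx(10 * params.theta9)
    assert rd.memory_time(0.0, params) == params.M_min


def test_let_it_go():
    assert rd.let_it_go(0.0, 5.0) == 0.0
    assert rd.let_it_go(14.0, 7.0) == 2.0
    # steady-state outflow balances the inflow
    assert rd.let_it_go(12.605, 15.217) == pytest.approx(GIRL_U, abs=2e-4)
    with pytest.raises(ValueError):
        rd.let_it_go(1.0, 0.0)
    with pytest.raises(ValueError):
        rd.let_it_go(-1.0, 5.0)


# ---------------------------------------------------------------------------
# noise process


def test_ou_step_sigma_zero_decays_geometrically(params):
    eps = 3.0
    factor = 1 - params.dt / params.theta12
    for _ in range(5):
        new = rd.ou_step(eps, 0.0, params.theta12, params.dt, draw=123.4)
        assert new == pytest.approx(eps * factor)
        eps = new


def test_ou_step_rejects_bad_configuration():
    with pytest.raises(ValueError):
        rd.ou_step(0.0, 1.0, corr_time=0.1, dt=0.125, draw=0.0)
    with pytest.raises(ValueError):
        rd.ou_step(0.0, -1.0, corr_time=2.0, dt=0.125, draw=0.0)


def test_ou_path_matches_iterated_ou_step(params):
    rng = np.random.default_rng(7)
    n = 64
    path = rd.ou_path(n, params.theta10, params.theta12, params.dt, rng, eps0=1.5)
    rng2 = np.random.default_rng(7)
    draws = rng2.standard_normal(n)
    eps = 1.5
    manual = [eps]
    for z in draws:
        eps = rd.ou_step(eps, params.theta10, params.theta12, params.dt, z)
        manual.append(eps)
    np.testing.assert_allclose(path, manual, rtol=1e-12)


def test_ou_path_stationary_moments(params):
    # closed-form stationary SD and lag-1-step autocorrelation
    rng = np.random.default_rng(11)
    sigma, tc, dt = params.theta10, params.theta12, params.dt
    path = rd.ou_path(200_000, sigma, tc, dt, rng, eps0=rng.standard_normal() * sigma)
    assert np.std(path) == pytest.approx(sigma, rel=0.02)
    a_expect = 1 - dt / tc
    a_hat = np.corrcoef(path[:-1], path[1:])[0, 1]
    assert a_hat == pytest.approx(a_expect, abs=0.01)


# ---------------------------------------------------------------------------
# stepping and simulation


def test_step_holds_exact_fixed_point(params):
    ss = rd.steady_state(params, G=1, u=GIRL_U)
    prof = rd.IndividualProfile(1, ss.D, ss.R, ss.S, inflow=GIRL_U)
    state = rd.SystemState(0.0, ss.D, ss.R, ss.S)
    new = rd.step(state, prof, params, rng=None)
    assert new.D == pytest.approx(ss.D, abs=1e-12)
    assert new.R == pytest.approx(ss.R, abs=1e-12)
    assert new.S == pytest.approx(ss.S, abs=1e-12)


def test_step_euler_arithmetic_on_stressor_stock(params):
    # with rumination frozen so that M = 7: S' = 14 - (14/7)*0.125 = 13.75
    p = params.with_theta(theta9=0.7)  # M = 0.7 * 10 = 7 at R = 10
    p = replace(p, tau_R=1.0)
    prof = rd.IndividualProfile(1, 0.0, 10.0, 14.0, inflow=0.0)
    state = rd.SystemState(0.0, 0.0, 10.0, 14.0)
    new = rd.step(state, prof, p, rng=None)
    assert new.S == pytest.approx(14.0 - 2.0 * 0.125)


def test_step_clamps_to_upper_bound(params):
    p = params.with_theta(theta6=1000.0)  # huge indicated depression
    prof = rd.IndividualProfile(0, 52.0, 5.0, 0.0)
    state = rd.SystemState(0.0, 52.0, 5.0, 0.0)
    new = rd.step(state, prof, p, rng=None)
    assert new.D == p.D_bounds[1]


def test_simulate_deterministic_under_seed(params):
    prof = rd.IndividualProfile(1, 16.0, 12.0, 5.0, inflow=0.5)
    a = rd.simulate(prof, params, 24, seed=42)
    b = rd.simulate(prof, params, 24, seed=42)
    np.testing.assert_array_equal(a.D, b.D)
    np.testing.assert_array_equal(a.epsR, b.epsR)
    c = rd.simulate(prof, params, 24, seed=43)
    assert not np.array_equal(a.D, c.D)


@pytest.mark.parametrize("gender,u,start", [
    (1, GIRL_U, (5.0, 5.0, 5.0)),
    (1, GIRL_U, (30.0, 25.0, 0.0)),
    (0, 0.0, (20.0, 15.0, 10.0)),
])
def test_noise_free_simulation_converges_to_analytic_fixed_point(params, gender, u, start):
    ss = rd.steady_state(params, gender, u)
    prof = rd.IndividualProfile(gender, *start, inflow=u)
    tr = rd.simulate(prof, params, 600, noise=False)
    assert tr.D[-1] == pytest.approx(ss.D, abs=1e-2)
    assert tr.R[-1] == pytest.approx(ss.R, abs=5e-3)
    assert tr.S[-1] == pytest.approx(ss.S, abs=1e-2)


def test_scalar_and_batch_engines_agree(params):
    prof = rd.IndividualProfile(1, 16.43, 20.49, 11.25, inflow=1.875)
    tr = rd.simulate(prof, params, 60, noise=False)
    sim = rd.simulate_batch(np.array([prof.D0]), np.array([prof.R0]),
                            np.array([prof.S0]), np.array([1.0]),
                            np.array([1.875]), params, 60)
    np.testing.assert_array_equal(sim["D"][:, 0], tr.D)
    np.testing.assert_array_equal(sim["R"][:, 0], tr.R)
    np.testing.assert_array_equal(sim["S"][:, 0], tr.S)


def test_stressor_stock_conservation(params):
    # S(T) - S(0) equals the Euler sum of (u - let_it_go)*dt on clamp-free runs
    prof = rd.IndividualProfile(1, 10.0, 12.0, 8.0, inflow=0.9)
    tr = rd.simulate(prof, params, 48, seed=5)
    assert np.all(tr.S > 0)  # no clamping events on this path
    net = np.sum((0.9 - tr.S[:-1] / tr.M[:-1]) * params.dt)
    assert tr.S[-1] - tr.S[0] == pytest.approx(net, abs=1e-9)


def test_dt_refinement_stability(params):
    prof = rd.IndividualProfile(1, 16.43, 20.49, 11.25, inflow=1.875)
    coarse = rd.simulate(prof, params, 60, noise=False)
    fine = rd.simulate(prof, replace(params, dt=params.dt / 2), 60, noise=False)
    for series_c, series_f in ((coarse.D, fine.D), (coarse.R, fine.R), (coarse.S, fine.S)):
        rel = np.abs(series_f[::2] - series_c) / np.maximum(np.abs(series_c), 1.0)
        assert rel.max() < 0.01


def test_terminal_depression_monotone_in_drivers(params):
    # non-decreasing in inflow and initial rumination; girls above boys
    def term_D(gender, R0, u):
        prof = rd.IndividualProfile(gender, 9.98, R0, 4.97, inflow=u)
        return rd.simulate(prof, params, 120, noise=False).D[-1]

    us = [0.0, 0.4, 0.8, 1.2]
    for lo, hi in zip(us[:-1], us[1:]):
        assert term_D(1, 12.78, lo) <= term_D(1, 12.78, hi) + 1e-9
    r0s = [2.0, 8.0, 14.0, 20.0]
    for lo, hi in zip(r0s[:-1], r0s[1:]):
        assert term_D(1, lo, 0.9) <= term_D(1, hi, 0.9) + 1e-9
    assert term_D(1, 12.0, 0.8) >= term_D(0, 12.0, 0.8)


def test_longer_memory_time_keeps_stressors_alive(params):
    # raising theta9 strengthens the rumination loop: terminal S and D rise
    prof = rd.IndividualProfile(1, 9.98, 12.78, 4.97, inflow=0.6)
    lo = rd.simulate(prof, params.with_theta(theta9=1.0), 120, noise=False)
    hi = rd.simulate(prof, params.with_theta(theta9=1.4741), 120, noise=False)
    assert hi.S[-1] >= lo.S[-1] - 1e-9
    assert hi.D[-1] >= lo.D[-1] - 1e-9


def test_trajectory_derived_series_and_export(params):
    prof = rd.IndividualProfile(0, 8.0, 10.0, 3.0, inflow=0.2)
    tr = rd.simulate(prof, params, 12, seed=9)
    np.testing.assert_allclose(tr.M, np.maximum(params.theta9 * tr.R, params.M_min))
    np.testing.assert_allclose(tr.L, tr.S / tr.M)
    df = tr.to_frame()
    assert list(df.columns) == ["t", "D", "R", "S", "epsR", "epsD", "M", "L"]
    assert np.all(np.diff(df["t"]) > 0)


# ---------------------------------------------------------------------------
# analytic fixed point


def test_steady_state_hand_solved_values(params):
    ss = rd.steady_state(params, G=1, u=GIRL_U)
    assert not ss.diverges
    assert (ss.D, ss.R, ss.S) == pytest.approx((9.897, 10.323, 12.605), abs=1e-3)
    boy = rd.steady_state(params, G=0, u=0.0)
    assert (boy.D, boy.R, boy.S) == pytest.approx((3.571, 0.3135, 0.0), abs=1e-3)


def test_steady_state_divergence_flag(params):
    ss = rd.steady_state(params, G=1, u=1.875)
    assert ss.diverges
    assert ss.loop_gain == pytest.approx(0.1639 + 0.2677 + 0.6960, abs=2e-4)
    assert math.isnan(ss.D)


def test_steady_state_decoupled_case(params):
    p = params.with_theta(theta2=0.0, theta4=0.0, theta5=0.0)
    for G in (0, 1):
        ss = rd.steady_state(p, G=G, u=0.5)
        assert ss.R == pytest.approx(p.theta1 + p.theta3 * G)


def test_steady_state_rejects_explosive_theta8(params):
    with pytest.raises(ValueError):
        rd.steady_state(params.with_theta(theta8=1.0), G=0, u=0.0)


def test_divergent_trajectory_grows_until_clamped(params):
    prof = rd.IndividualProfile(1, 16.43, 20.49, 56.6, inflow=1.875)
    tr = rd.simulate(prof, params, 240, noise=False)
    assert tr.R[-1] == params.R_bounds[1]  # rumination pinned at the scale top
    assert np.all(np.diff(tr.D[8:]) >= -1e-9)  # growth from month 1 onward


@settings(max_examples=25, deadline=None)
@given(
    theta5=st.floats(-0.5, 0.6),
    theta8=st.floats(0.0, 0.95),
    u=st.floats(0.0, 1.5),
    G=st.sampled_from([0, 1]),
)
def test_steady_state_satisfies_defining_equations(theta5, theta8, u, G):
    p = rd.ModelParams.defaults().with_theta(theta5=theta5, theta8=theta8)
    ss = rd.steady_state(p, G=G, u=u)
    if ss.diverges:
        assert ss.loop_gain >= 1.0
        return
    assert rd.indicated_rumination(ss.D, ss.R, ss.S, G, 0.0, p) == pytest.approx(
        ss.R, abs=1e-8)
    assert rd.indicated_depression(ss.D, ss.R, 0.0, p) == pytest.approx(ss.D, abs=1e-8)
    M = rd.memory_time(ss.R, p)
    assert u - rd.let_it_go(ss.S, M) == pytest.approx(0.0, abs=1e-8)


@settings(max_examples=20, deadline=None)
@given(seed=st.integers(0, 10_000), u=st.floats(0.0, 2.0))
def test_stocks_always_within_clamp_bounds(seed, u):
    p = rd.ModelParams.defaults()
    prof = rd.IndividualProfile(1, 10.0, 12.0, 6.0, inflow=u)
    tr = rd.simulate(prof, p, 24, seed=seed)
    assert np.all((tr.D >= p.D_bounds[0]) & (tr.D <= p.D_bounds[1]))
    assert np.all((tr.R >= p.R_bounds[0]) & (tr.R <= p.R_bounds[1]))
    assert np.all(tr.S >= 0)


# ---------------------------------------------------------------------------
# parameter validation


def test_params_validation():
    with pytest.raises(ValueError):
        rd.ModelParams(theta9=-1.0)
    with pytest.raises(ValueError):
        rd.ModelParams(theta12=0.0)
    with pytest.raises(ValueError):
        rd.ModelParams(dt=0.5)  # violates dt <= min(tau, theta12)/4
    with pytest.raises(ValueError):
        rd.ModelParams(theta10=-0.1)


def test_params_json_round_trip(tmp_path, params):
    path = tmp_path / "p.json"
    rd.save_params(params, path)
    again = rd.load_params(path)
    assert again == params


def test_ou_coeffs_variance_matching(params):
    # the AR(1) stationary variance q^2/(1-a^2) equals sigma^2 exactly
    a, q = _ou_coeffs(params.theta10, params.theta12, params.dt)
    assert q**2 / (1 - a**2) == pytest.approx(params.theta10**2, rel=1e-12)
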