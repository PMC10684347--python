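"""Core dynamical system: degradation profile, ODEs, RK4 integration."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import chm
from chm.core_model import phase_step_counts, zt_to_step_index
from chm.errors import ConfigurationError, DomainError, ValidationError

from conftest import random_homeostatic_params


def homeostasis_beta_oracle(core, cond, t_grid):
    """Numerically solve for the degradation rate that keeps dS/dt = 0.

    On the homeostatic orbit the sucrose balance fixes the degradation flux
    directly: deg = H*S0 - a*(1-gamma) in the light and deg = H*S0 in the
    dark, with S0 = a*tau_L/H. Starch follows by integrating dC/dt with
    that flux from C(0) = 1/beta_p; beta(t) = deg(t)/C(t)**kappa. This
    never touches the closed form under test.
    """
    a, g, bp, k = core.a, core.gamma, core.beta_p, core.kappa
    P, tau, H = cond.photoperiod_ext, cond.tau_L, cond.H
    S0 = a * tau / H
    deg = np.where(t_grid < P, H * S0 - a * (1 - g), H * S0)
    dcdt_light = a * g - (H * S0 - a * (1 - g))
    dcdt_dark = -H * S0
    # dC/dt is piecewise constant, so its cumulative integral is exact
    C = (1.0 / bp + dcdt_light * np.minimum(t_grid, P)
         + dcdt_dark * np.maximum(t_grid - P, 0.0))
    return deg / C ** k


class TestDegradationRate:
    def test_dark_limit_at_dawn(self):
        core = chm.CoreParams(a=1.0, gamma=0.5, beta_p=1.0)
        cond = chm.ConditionParams(H=1.0, tau_L=2 / 3, photoperiod_ext=2 / 3)
        val = chm.degradation_rate(core, cond, 1.0 - 1e-12)
        assert val == pytest.approx(2 / 3, rel=1e-9)

    def test_light_onset(self):
        core = chm.CoreParams(a=1.0, gamma=0.5, beta_p=1.0)
        cond = chm.ConditionParams(H=1.0, tau_L=2 / 3, photoperiod_ext=2 / 3)
        assert chm.degradation_rate(core, cond, 0.0) == pytest.approx(1 / 6)

    def test_zero_light_rate_at_short_photoperiod_boundary(self):
        # tau_L = 1 - gamma: the light-phase numerator vanishes
        core = chm.CoreParams(a=2.0, gamma=0.5, beta_p=1.5)
        cond = chm.ConditionParams(H=1.0, tau_L=0.5, photoperiod_ext=0.5)
        for t in (0.0, 0.2, 0.49):
            assert chm.degradation_rate(core, cond, t) == 0.0

    def test_clamped_below_boundary(self):
        core = chm.CoreParams(a=2.0, gamma=0.4, beta_p=1.0)
        cond = chm.ConditionParams(H=1.0, tau_L=0.3, photoperiod_ext=0.3)
        assert chm.degradation_rate(core, cond, 0.1) == 0.0
        # dark formula is retained unchanged
        assert chm.degradation_rate(core, cond, 0.9) > 0.0

    def test_invalid_time_raises(self):
        core = chm.CoreParams(a=1.0, gamma=0.5, beta_p=1.0)
        cond = chm.ConditionParams(H=1.0, tau_L=0.5, photoperiod_ext=0.5)
        for bad in (-0.1, 1.0, 1.5, np.nan):
            with pytest.raises(DomainError):
                chm.degradation_rate(core, cond, bad)

    def test_matches_numerical_homeostasis_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(10):
            core, cond = random_homeostatic_params(rng)
            t = np.linspace(0.0, 1.0, 2001)[:-1]
            oracle = homeostasis_beta_oracle(core, cond, t)
            closed = chm.degradation_rate(core, cond, t)
            scale = oracle.max()
            assert np.max(np.abs(closed - oracle)) < 1e-6 * scale

    def test_monotone_decreasing_light_increasing_dark_peak_at_dawn(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            core, cond = random_homeostatic_params(rng)
            P = cond.photoperiod_ext
            t_light = np.linspace(0, P, 200, endpoint=False)
            t_dark = np.linspace(P, 1, 200, endpoint=False)
            bl = chm.degradation_rate(core, cond, t_light)
            bd = chm.degradation_rate(core, cond, t_dark)
            assert np.all(np.diff(bl) <= 1e-12)
            assert np.all(np.diff(bd) >= -1e-12)
            dawn = chm.degradation_rate(core, cond, 1.0 - 1e-9)
            assert dawn >= max(bl.max(), bd.max()) - 1e-9


class TestOdeRhs:
    def test_zero_starch_no_degradation(self):
        core = chm.CoreParams(a=1.0, gamma=0.4, beta_p=1.0)
        cond = chm.ConditionParams(H=2.0, tau_L=0.6, photoperiod_ext=0.5)
        dC, dS = chm.ode_rhs((0.0, 0.2), 0.1, core, cond)
        assert dC == pytest.approx(core.a * core.gamma)
        dC_dark, _ = chm.ode_rhs((0.0, 0.2), 0.7, core, cond)
        assert dC_dark == 0.0

    def test_direct_substitution(self):
        core = chm.CoreParams(a=1.0, gamma=0.4, beta_p=1.0)
        cond = chm.ConditionParams(H=2.0, tau_L=0.6, photoperiod_ext=0.5)
        # choose beta_fn and C so the degradation flux is exactly 0.1
        dC, dS = chm.ode_rhs((1.0, 0.2), 0.1, core, cond,
                             beta_fn=lambda t: 0.1)
        assert dC == pytest.approx(0.4 - 0.1)
        assert dS == pytest.approx(0.6 + 0.1 - 0.4)

    def test_homeostatic_sucrose_balance(self):
        core = chm.CoreParams(a=3.0, gamma=0.6, beta_p=1.2)
        P = 14 / 24
        cond = chm.ConditionParams(H=2.5, tau_L=P, photoperiod_ext=P)
        C0, S0 = chm.homeostatic_initial_state(core, cond)
        # along the orbit C(t) is the closed-form linear profile
        for t in (0.0, 0.2, P - 1e-6, P, 0.8, 0.999):
            if t < P:
                C = C0 + core.a * (1 - P) * t
            else:
                C = (core.a * core.beta_p * P * (1 - t) + 1) / core.beta_p
            _, dS = chm.ode_rhs((C, S0), t, core, cond)
            assert abs(dS) < 1e-9

    def test_negative_state_raises(self):
        core = chm.CoreParams(a=1.0, gamma=0.5, beta_p=1.0)
        cond = chm.ConditionParams(H=1.0, tau_L=0.5, photoperiod_ext=0.5)
        with pytest.raises(ValidationError):
            chm.ode_rhs((-0.1, 0.2), 0.1, core, cond)


class TestInitialState:
    def test_printed_formula(self):
        core = chm.CoreParams(a=1.0, gamma=0.5, beta_p=1.0)
        cond = chm.ConditionParams(H=2.0, tau_L=0.5, photoperiod_ext=0.5)
        assert chm.homeostatic_initial_state(core, cond) == (1.0, 0.25)

    @pytest.mark.parametrize("beta_p,expected_c0", [(4.0, 0.25), (0.5, 2.0)])
    def test_dawn_starch_is_inverse_potential(self, beta_p, expected_c0):
        core = chm.CoreParams(a=1.0, gamma=0.5, beta_p=beta_p)
        cond = chm.ConditionParams(H=2.0, tau_L=0.5, photoperiod_ext=0.5)
        assert chm.homeostatic_initial_state(core, cond)[0] == expected_c0

    def test_sucrose_level(self):
        core = chm.CoreParams(a=2.0, gamma=0.5, beta_p=1.0)
        cond = chm.ConditionParams(H=1.0, tau_L=2 / 3, photoperiod_ext=0.5)
        assert chm.homeostatic_initial_state(core, cond)[1] == pytest.approx(4 / 3)


def _theta_for(core, cond):
    other_label = "SD" if cond.condition_label == "LD" else "LD"
    other = chm.ConditionParams(H=cond.H, tau_L=cond.tau_L,
                                photoperiod_ext=cond.photoperiod_ext,
                                condition_label=other_label)
    ld, sd = (cond, other) if cond.condition_label == "LD" else (other, cond)
    return chm.ThetaFull(core=core, ld=ld, sd=sd, sigma_c2=1e-4, sigma_s2=1e-4)


class TestSimulate:
    def test_homeostatic_sucrose_constant_and_starch_linear(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            core, cond = random_homeostatic_params(rng)
            theta = _theta_for(core, cond)
            traj = chm.simulate(theta, cond, n_days=6)
            S0 = core.a * cond.tau_L / cond.H
            assert np.max(np.abs(traj.S - S0)) < 1e-6 * S0
            # slopes: a(1-tau) in light, -a*tau in dark
            day = traj.final_day()
            spd = day.steps_per_day
            n_light = int(round(cond.photoperiod_ext * spd))
            dC = np.diff(day.C) * spd
            assert np.allclose(dC[:n_light], core.a * (1 - cond.tau_L),
                               rtol=1e-6)
            assert np.allclose(dC[n_light:], -core.a * cond.tau_L, rtol=1e-6)
            # daily periodicity
            assert day.C[0] == pytest.approx(day.C[-1], rel=1e-9)

    def test_daily_carbon_balance_on_orbit(self):
        """Carbon fixed into starch over the light phase equals carbon
        degraded out of starch over the whole day on the homeostatic orbit."""
        from scipy.integrate import simpson

        from chm._kernels import beta_closed_form

        rng = np.random.default_rng(5)
        core, cond = random_homeostatic_params(rng)
        theta = _theta_for(core, cond)
        day = chm.simulate(theta, cond, n_days=6).final_day()
        t = day.times
        n_light = int(round(cond.photoperiod_ext * day.steps_per_day))
        args = (core.a, core.gamma, core.beta_p, core.kappa, cond.tau_L)
        # integrate per phase (the integrand is smooth within each phase)
        beta_l = np.array([beta_closed_form(ti, True, *args)
                           for ti in t[: n_light + 1]])
        beta_d = np.array([beta_closed_form(ti, False, *args)
                           for ti in t[n_light:]])
        deg_l = beta_l * day.C[: n_light + 1] ** core.kappa
        deg_d = beta_d * day.C[n_light:] ** core.kappa
        total_deg = simpson(deg_l, x=t[: n_light + 1]) + simpson(
            deg_d, x=t[n_light:])
        fixed = core.a * core.gamma * cond.photoperiod_ext
        assert total_deg == pytest.approx(fixed, rel=1e-6)

    def test_rk4_step_halving_convergence(self, theta_default):
        cond = theta_default.ld
        coarse = chm.simulate(theta_default, cond, n_days=3, dt=1 / 720)
        fine = chm.simulate(theta_default, cond, n_days=3, dt=1 / 1440)
        spd_ratio = 2
        c_day = coarse.final_day()
        f_day = fine.final_day()
        diff = np.max(np.abs(c_day.C - f_day.C[::spd_ratio]))
        assert diff < 1e-8 * np.max(f_day.C)

    def test_misaligned_step_raises(self, theta_default):
        with pytest.raises(ConfigurationError):
            chm.simulate(theta_default, theta_default.ld, dt=1 / 100.0)
        with pytest.raises(ConfigurationError):
            chm.simulate(theta_default, theta_default.ld, dt=0.7 / 1440)

    def test_nonnegative_states(self, theta_default):
        # strong degradation potential, short subjective photoperiod
        core = chm.CoreParams(a=8.0, gamma=0.9, beta_p=15.0)
        cond = chm.ConditionParams(H=1.0, tau_L=20 / 24,
                                   photoperiod_ext=8 / 24,
                                   condition_label="SD")
        theta = _theta_for(core, cond)
        traj = chm.simulate(theta, cond, n_days=6)
        assert np.all(traj.C >= 0)
        assert np.all(traj.S >= 0)


class TestPredictedProfile:
    def test_periodicity_and_sucrose_level(self, theta_default):
        zts = [0, 4, 8, 16, 24]
        muC, muS = chm.predicted_profile(theta_default, theta_default.ld, zts)
        assert muC[0] == pytest.approx(muC[-1], rel=1e-9)
        S0 = theta_default.core.a * theta_default.ld.tau_L / theta_default.ld.H
        assert np.allclose(muS, S0, rtol=1e-6)

    def test_mismatched_subjective_photoperiod_breaks_homeostasis(
            self, theta_default):
        theta = theta_default.with_params(
            theta_default.param_vector() + np.array([0, 0, 0, -2 / 24, 0, 0, 0]))
        _, muS = chm.predicted_profile(theta, theta.ld,
                                       np.arange(0, 25, 2))
        assert np.ptp(muS) > 1e-3

    def test_off_grid_sample_time_raises(self, theta_default):
        with pytest.raises(ConfigurationError):
            chm.predicted_profile(theta_default, theta_default.ld, [0.37],
                                  steps_per_day=96)
        with pytest.raises(DomainError):
            chm.predicted_profile(theta_default, theta_default.ld, [25.0])


class TestValidation:
    @pytest.mark.parametrize("kwargs", [
        {"a": -1.0, "gamma": 0.5, "beta_p": 1.0},
        {"a": 1.0, "gamma": 1.5, "beta_p": 1.0},
        {"a": 1.0, "gamma": 0.5, "beta_p": 0.0},
        {"a": np.inf, "gamma": 0.5, "beta_p": 1.0},
        {"a": 1.0, "gamma": 0.5, "beta_p": 1.0, "kappa": 1.5},
    ])
    def test_core_params_rejected(self, kwargs):
        with pytest.raises(ValidationError):
            chm.CoreParams(**kwargs)

    @pytest.mark.parametrize("kwargs", [
        {"H": 0.0, "tau_L": 0.5, "photoperiod_ext": 0.5},
        {"H": 1.0, "tau_L": 1.2, "photoperiod_ext": 0.5},
        {"H": 1.0, "tau_L": 0.5, "photoperiod_ext": 1.0},
        {"H": 1.0, "tau_L": 0.5, "photoperiod_ext": 0.5,
         "condition_label": "MD"},
    ])
    def test_condition_params_rejected(self, kwargs):
        with pytest.raises(ValidationError):
            chm.ConditionParams(**kwargs)

    def test_theta_vector_roundtrip(self, theta_default):
        vec = theta_default.param_vector()
        theta2 = chm.ThetaFull.from_vectors(vec, 0.1, 0.05)
        assert np.allclose(theta2.param_vector(), vec)
        assert theta2.sigma_c2 == pytest.approx(0.01)


@settings(max_examples=25, deadline=None)
@given(st.floats(0.31, 0.9), st.integers(5, 20), st.floats(0.3, 3.0),
       st.floats(1.0, 10.0), st.floats(0.5, 8.0))
def test_property_homeostatic_orbit_is_flat_in_sucrose(gamma, p_hours, beta_p,
                                                       a, H):
    """For any valid parameters with tau_L = external photoperiod >= 1-gamma,
    sucrose stays at a*tau_L/H along the whole simulated trajectory."""
    P = p_hours / 24.0
    if P < 1 - gamma + 1e-3:
        return
    core = chm.CoreParams(a=a, gamma=gamma, beta_p=beta_p)
    cond = chm.ConditionParams(H=H, tau_L=P, photoperiod_ext=P)
    theta = _theta_for(core, cond)
    traj = chm.simulate(theta, cond, n_days=4, dt=1 / 1440)
    S0 = a * P / H
    assert np.max(np.abs(traj.S - S0)) < 1e-6 * S0
    assert np.all(traj.C >= 0)


def test_phase_step_helpers():
    assert phase_step_counts(16 / 24, 96) == (64, 32)
    assert phase_step_counts(8 / 24, 1440) == (480, 960)
    with pytest.raises(ConfigurationError):
        phase_step_counts(16 / 24, 100)
    idx = zt_to_step_index([0, 12, 24], 96)
    assert list(idx) == [0, 48, 96]
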