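"""Numba-compiled numerical core: degradation profile, RK4 integration, likelihood.

Everything here works in model time units (day = 1). The integration grid is a
fixed step ``dt`` that must divide both the light and the dark phase exactly so
that no RK4 step straddles the light/dark discontinuity; phase membership is
passed explicitly per segment rather than inferred from ``t`` so the switch
point itself is unambiguous.
"""

import numba
import numpy as np

__all__ = [
    "beta_closed_form",
    "simulate_days",
    "mu_at_obs",
    "loglik_pointwise_many",
]


@numba.njit(cache=True)
def _beta(t, light, a, gamma, beta_p, kappa, tau_L):
    """Homeostatic degradation rate at time-of-day t (fraction of day).

    Light branch is clamped to 0 when tau_L < 1 - gamma (extremely short
    subjective photoperiod: the homeostatic light-phase rate would be
    negative, so degradation shuts off in the light instead).
    """
    if light:
        num = a * (gamma - 1.0 + tau_L)
        if num <= 0.0:
            return 0.0
        den = (a * beta_p * (1.0 - tau_L) * t + 1.0) ** kappa
        return num * beta_p ** kappa / den
    else:
        den = (a * beta_p * tau_L * (1.0 - t) + 1.0) ** kappa
        return a * tau_L * beta_p ** kappa / den


@numba.njit(cache=True)
def beta_closed_form(t, light, a, gamma, beta_p, kappa, tau_L):
    return _beta(t, light, a, gamma, beta_p, kappa, tau_L)


@numba.njit(cache=True)
def _rhs(C, S, t, light, a, gamma, beta_p, kappa, H, tau_L, flux_cap):
    b = _beta(t, light, a, gamma, beta_p, kappa, tau_L)
    Cp = C if C > 0.0 else 0.0
    deg = b * Cp ** kappa
    capped = False
    if deg > flux_cap:
        deg = flux_cap
        capped = True
    if light:
        dC = a * gamma - deg
        dS = a * (1.0 - gamma) + deg - H * S
    else:
        dC = -deg
        dS = deg - H * S
    return dC, dS, capped


@numba.njit(cache=True)
def _rk4_segment(C, S, t0, n_steps, dt, light, a, gamma, beta_p, kappa, H,
                 tau_L, out_C, out_S, offset):
    """Integrate one constant-phase segment; store states after each step.

    Returns (C, S, n_capped). The degradation flux within a step is capped at
    C/dt so starch cannot be driven negative by a coarse step.
    """
    n_cap = 0
    for i in range(n_steps):
        t = t0 + i * dt
        cap = (C / dt) if C > 0.0 else 0.0
        k1C, k1S, c1 = _rhs(C, S, t, light, a, gamma, beta_p, kappa, H, tau_L, cap)
        k2C, k2S, c2 = _rhs(C + 0.5 * dt * k1C, S + 0.5 * dt * k1S, t + 0.5 * dt,
                            light, a, gamma, beta_p, kappa, H, tau_L, cap)
        k3C, k3S, c3 = _rhs(C + 0.5 * dt * k2C, S + 0.5 * dt * k2S, t + 0.5 * dt,
                            light, a, gamma, beta_p, kappa, H, tau_L, cap)
        k4C, k4S, c4 = _rhs(C + dt * k3C, S + dt * k3S, t + dt,
                            light, a, gamma, beta_p, kappa, H, tau_L, cap)
        C = C + dt / 6.0 * (k1C + 2.0 * k2C + 2.0 * k3C + k4C)
        S = S + dt / 6.0 * (k1S + 2.0 * k2S + 2.0 * k3S + k4S)
        if c1 or c2 or c3 or c4:
            n_cap += 1
        if C < 0.0:
            C = 0.0
        if S < 0.0:
            S = 0.0
        out_C[offset + i] = C
        out_S[offset + i] = S
    return C, S, n_cap


@numba.njit(cache=True)
def simulate_days(a, gamma, beta_p, kappa, H, tau_L, P,
                  C0, S0, n_days, n_light, n_dark):
    """Fixed-step RK4 over n_days diel cycles.

    n_light / n_dark are the per-phase step counts; dt = P/n_light must equal
    (1-P)/n_dark. Returns (C, S, n_capped) with C[0], S[0] the initial state
    and one entry per step thereafter (length n_days*(n_light+n_dark)+1).
    """
    per_day = n_light + n_dark
    n_tot = n_days * per_day + 1
    C_arr = np.empty(n_tot)
    S_arr = np.empty(n_tot)
    C_arr[0] = C0
    S_arr[0] = S0
    dt = 1.0 / per_day if n_light + n_dark > 0 else 0.0
    dt_light = P / n_light
    dt_dark = (1.0 - P) / n_dark
    C = C0
    S = S0
    n_cap = 0
    for d in range(n_days):
        off = d * per_day + 1
        C, S, c = _rk4_segment(C, S, 0.0, n_light, dt_light, True,
                               a, gamma, beta_p, kappa, H, tau_L,
                               C_arr, S_arr, off)
        n_cap += c
        C, S, c = _rk4_segment(C, S, P, n_dark, dt_dark, False,
                               a, gamma, beta_p, kappa, H, tau_L,
                               C_arr, S_arr, off + n_light)
        n_cap += c
    return C_arr, S_arr, n_cap


@numba.njit(cache=True)
def mu_at_obs(a, gamma, beta_p, kappa, H, tau_L, P,
              n_days, n_light, n_dark, obs_idx):
    """Model means (C, S) at final-day step indices obs_idx (0..steps/day).

    Initial state is the homeostatic steady state (C=1/beta_p, S=a*tau_L/H);
    the burn-in days let the trajectory relax to its periodic orbit when the
    parameters are away from perfect homeostasis.
    """
    C_arr, S_arr, n_cap = simulate_days(a, gamma, beta_p, kappa, H, tau_L, P,
                                        1.0 / beta_p, a * tau_L / H,
                                        n_days, n_light, n_dark)
    per_day = n_light + n_dark
    base = (n_days - 1) * per_day
    m = obs_idx.shape[0]
    muC = np.empty(m)
    muS = np.empty(m)
    for k in range(m):
        muC[k] = C_arr[base + obs_idx[k]]
        muS[k] = S_arr[base + obs_idx[k]]
    return muC, muS, n_cap


@numba.njit(cache=True)
def _loglik_condition(a, gamma, beta_p, kappa, H, tau_L, P,
                      n_days, n_light, n_dark, obs_idx,
                      obs_C, obs_S, sig_c2, sig_s2, out, off):
    """Pointwise Gaussian log-densities for one condition, written into out.

    Layout: starch observations first, then sucrose, matching obs_idx order.
    """
    muC, muS, _ = mu_at_obs(a, gamma, beta_p, kappa, H, tau_L, P,
                            n_days, n_light, n_dark, obs_idx)
    m = obs_idx.shape[0]
    c_norm = -0.5 * np.log(2.0 * np.pi * sig_c2)
    s_norm = -0.5 * np.log(2.0 * np.pi * sig_s2)
    for k in range(m):
        r = obs_C[k] - muC[k]
        out[off + k] = c_norm - 0.5 * r * r / sig_c2
    for k in range(m):
        r = obs_S[k] - muS[k]
        out[off + m + k] = s_norm - 0.5 * r * r / sig_s2
    return off + 2 * m


@numba.njit(cache=True)
def loglik_pointwise_many(theta, kappa,
                          P_ld, nl_ld, nd_ld, idx_ld, obsC_ld, obsS_ld,
                          P_sd, nl_sd, nd_sd, idx_sd, obsC_sd, obsS_sd,
                          n_days):
    """Pointwise log-likelihood for a batch of parameter vectors.

    theta rows: (a, gamma, H_ld, tau_ld, H_sd, tau_sd, beta_p, sig_c, sig_s).
    Returns (n_rows, n_obs) with the LD starch block, LD sucrose block, SD
    starch block, SD sucrose block concatenated.
    """
    n = theta.shape[0]
    n_obs = 2 * idx_ld.shape[0] + 2 * idx_sd.shape[0]
    out = np.empty((n, n_obs))
    for i in range(n):
        a = theta[i, 0]
        gamma = theta[i, 1]
        H_ld = theta[i, 2]
        tau_ld = theta[i, 3]
        H_sd = theta[i, 4]
        tau_sd = theta[i, 5]
        beta_p = theta[i, 6]
        sig_c2 = theta[i, 7] * theta[i, 7]
        sig_s2 = theta[i, 8] * theta[i, 8]
        off = _loglik_condition(a, gamma, beta_p, kappa, H_ld, tau_ld, P_ld,
                                n_days, nl_ld, nd_ld, idx_ld, obsC_ld, obsS_ld,
                                sig_c2, sig_s2, out[i], 0)
        _loglik_condition(a, gamma, beta_p, kappa, H_sd, tau_sd, P_sd,
                          n_days, nl_sd, nd_sd, idx_sd, obsC_sd, obsS_sd,
                          sig_c2, sig_s2, out[i], off)
    return out
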