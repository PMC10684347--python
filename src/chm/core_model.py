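"""Carbon-homeostasis dynamical system for diel starch/sucrose metabolism.

The model tracks leaf starch ``C`` and sucrose ``S`` over a 24 h light/dark
cycle, with time measured in fractions of a day (day = 1, dawn at t = 0).
Carbon is fixed photosynthetically at rate ``a`` during the light phase and
partitioned between starch (fraction ``gamma``) and sucrose. Starch is
degraded at the granule surface, so the degradation flux scales as
``C**kappa`` (kappa = 2/3 for spherical granules), with a clock-gated rate
profile ``beta_t`` whose closed form realizes sucrose homeostasis: constant
sucrose at ``a*tau_L/H`` when the subjective photoperiod ``tau_L`` matches
the external one. ``beta_t`` peaks at dawn and its trough timing is set by
``tau_L``; when ``tau_L < 1 - gamma`` (extremely short subjective
photoperiod) the light-phase rate is clamped to zero because the homeostatic
form would turn negative.

Dynamics (light / dark):

    dC/dt =  a*gamma - beta_t*C**kappa   /  -beta_t*C**kappa
    dS/dt =  a*(1-gamma) + beta_t*C**kappa - H*S  /  beta_t*C**kappa - H*S

Integration is fixed-step RK4 restarted at the light/dark switch so no step
straddles the discontinuity.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np

from . import _kernels
from .errors import ConfigurationError, DomainError, IntegrationError, ValidationError

logger = logging.getLogger(__name__)

#: Canonical order of the seven inferred model parameters.
PARAM_NAMES = ("a", "gamma", "H_LD", "tau_L_LD", "H_SD", "tau_L_SD", "beta_p")

#: Parameter order including the two noise standard deviations.
FULL_PARAM_NAMES = PARAM_NAMES + ("sigma_c", "sigma_s")

DEFAULT_STEPS_PER_DAY = 1440  # 1-minute RK4 steps
DEFAULT_N_DAYS = 6            # burn-in to the periodic orbit before read-out


def _require_finite(name: str, value: float) -> None:
    if not math.isfinite(value):
        raise ValidationError(f"{name} must be finite, got {value!r}")


@dataclass(frozen=True)
class CoreParams:
    """Condition-independent parameters of the carbon-homeostasis model.

    a : photosynthetic carbon fixation rate (carbon units per day), > 0.
    gamma : partitioning fraction of fixed carbon to starch, in [0, 1].
    beta_p : starch degradation potential (sets the dawn peak rate), > 0.
    kappa : granule-surface exponent (2/3 for spheres), in (0, 1].
    """

    a: float
    gamma: float
    beta_p: float
    kappa: float = 2.0 / 3.0

    def __post_init__(self) -> None:
        for name in ("a", "gamma", "beta_p", "kappa"):
            _require_finite(name, getattr(self, name))
        if self.a <= 0:
            raise ValidationError(f"a must be > 0, got {self.a}")
        if not 0.0 <= self.gamma <= 1.0:
            raise ValidationError(f"gamma must be in [0, 1], got {self.gamma}")
        if self.beta_p <= 0:
            raise ValidationError(f"beta_p must be > 0, got {self.beta_p}")
        if not 0.0 < self.kappa <= 1.0:
            raise ValidationError(f"kappa must be in (0, 1], got {self.kappa}")


@dataclass(frozen=True)
class ConditionParams:
    """Photoperiod-condition-specific parameters.

    H : sucrose consumption/export rate (per day), > 0.
    tau_L : subjective photoperiod as a fraction of the day, in [0, 1];
        the photoperiod implied by the plant's internal degradation schedule.
    photoperiod_ext : external light fraction of the day, in (0, 1).
    condition_label : "LD" or "SD".
    """

    H: float
    tau_L: float
    photoperiod_ext: float
    condition_label: str = "LD"

    def __post_init__(self) -> None:
        for name in ("H", "tau_L", "photoperiod_ext"):
            _require_finite(name, getattr(self, name))
        if self.H <= 0:
            raise ValidationError(f"H must be > 0, got {self.H}")
        if not 0.0 <= self.tau_L <= 1.0:
            raise ValidationError(f"tau_L must be in [0, 1], got {self.tau_L}")
        if not 0.0 < self.photoperiod_ext < 1.0:
            raise ValidationError(
                f"photoperiod_ext must be in (0, 1), got {self.photoperiod_ext}"
            )
        if self.condition_label not in ("LD", "SD"):
            raise ValidationError(
                f"condition_label must be 'LD' or 'SD', got {self.condition_label!r}"
            )


# External photoperiods of the study design: LD = 16 h light, SD = 8 h light.
LD_PHOTOPERIOD = 16.0 / 24.0
SD_PHOTOPERIOD = 8.0 / 24.0


@dataclass(frozen=True)
class ThetaFull:
    """The full parameter object of inference.

    Bundles the seven model parameters (a, gamma, H_LD, tau_L_LD, H_SD,
    tau_L_SD, beta_p) with the two measurement-noise variances (starch
    sigma_c2, sucrose sigma_s2).
    """

    core: CoreParams
    ld: ConditionParams
    sd: ConditionParams
    sigma_c2: float
    sigma_s2: float

    def __post_init__(self) -> None:
        if self.sigma_c2 <= 0 or self.sigma_s2 <= 0:
            raise ValidationError("noise variances must be > 0")
        if self.ld.condition_label != "LD" or self.sd.condition_label != "SD":
            raise ValidationError("ld/sd fields must carry matching condition labels")

    def condition(self, label: str) -> ConditionParams:
        if label == "LD":
            return self.ld
        if label == "SD":
            return self.sd
        raise ValidationError(f"unknown condition label {label!r}")

    def param_vector(self) -> np.ndarray:
        """The 7-vector (a, gamma, H_LD, tau_L_LD, H_SD, tau_L_SD, beta_p)."""
        return np.array([
            self.core.a, self.core.gamma,
            self.ld.H, self.ld.tau_L,
            self.sd.H, self.sd.tau_L,
            self.core.beta_p,
        ])

    def full_vector(self) -> np.ndarray:
        """The 9-vector: model parameters plus (sigma_c, sigma_s)."""
        return np.concatenate([
            self.param_vector(),
            [math.sqrt(self.sigma_c2), math.sqrt(self.sigma_s2)],
        ])

    @classmethod
    def from_vectors(cls, params: np.ndarray, sigma_c: float, sigma_s: float,
                     kappa: float = 2.0 / 3.0,
                     photoperiod_ld: float = LD_PHOTOPERIOD,
                     photoperiod_sd: float = SD_PHOTOPERIOD) -> "ThetaFull":
        a, gamma, h_ld, tau_ld, h_sd, tau_sd, beta_p = (float(x) for x in params)
        return cls(
            core=CoreParams(a=a, gamma=gamma, beta_p=beta_p, kappa=kappa),
            ld=ConditionParams(H=h_ld, tau_L=tau_ld,
                               photoperiod_ext=photoperiod_ld, condition_label="LD"),
            sd=ConditionParams(H=h_sd, tau_L=tau_sd,
                               photoperiod_ext=photoperiod_sd, condition_label="SD"),
            sigma_c2=float(sigma_c) ** 2,
            sigma_s2=float(sigma_s) ** 2,
        )

    def with_params(self, params: np.ndarray) -> "ThetaFull":
        """Copy of self with the 7 model parameters replaced."""
        a, gamma, h_ld, tau_ld, h_sd, tau_sd, beta_p = (float(x) for x in params)
        return ThetaFull(
            core=replace(self.core, a=a, gamma=gamma, beta_p=beta_p),
            ld=replace(self.ld, H=h_ld, tau_L=tau_ld),
            sd=replace(self.sd, H=h_sd, tau_L=tau_sd),
            sigma_c2=self.sigma_c2,
            sigma_s2=self.sigma_s2,
        )


@dataclass
class Trajectory:
    """Dense model solution over simulated days.

    times are in fractions of a day, cumulative over ``n_days`` (strictly
    increasing); C and S are the starch and sucrose concentrations.
    """

    times: np.ndarray
    C: np.ndarray
    S: np.ndarray
    condition: ConditionParams
    n_capped_steps: int = 0

    @property
    def steps_per_day(self) -> int:
        return int(round((len(self.times) - 1) / (self.times[-1] - self.times[0])))

    def final_day(self) -> "Trajectory":
        """The last simulated day, re-based to t in [0, 1]."""
        spd = self.steps_per_day
        sl = slice(len(self.times) - spd - 1, len(self.times))
        return Trajectory(self.times[sl] - self.times[sl][0], self.C[sl],
                          self.S[sl], self.condition, self.n_capped_steps)

    def to_frame(self):
        """Tidy table with columns day, zt_hour, C, S."""
        import pandas as pd

        day = np.floor(self.times - 1e-12).astype(int)
        day[0] = 0
        zt = (self.times - day) * 24.0
        return pd.DataFrame({"day": day, "zt_hour": zt, "C": self.C, "S": self.S})


def degradation_rate(core: CoreParams, cond: ConditionParams, t):
    """Clock-gated homeostatic starch degradation rate beta_t.

    ``t`` is time of day as a fraction in [0, 1); the light phase is
    [0, photoperiod_ext) and the dark phase [photoperiod_ext, 1), so the dawn
    peak is approached as t -> 1. Scalar or array ``t`` accepted.

    Light phase:  a*(gamma-1+tau_L)*beta_p**kappa / (a*beta_p*(1-tau_L)*t + 1)**kappa,
    clamped to 0 when tau_L < 1-gamma.
    Dark phase:   a*tau_L*beta_p**kappa / (a*beta_p*tau_L*(1-t) + 1)**kappa.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(~np.isfinite(t_arr)):
        raise DomainError("t must be finite")
    if np.any((t_arr < 0.0) | (t_arr >= 1.0)):
        raise DomainError(f"t must lie in [0, 1), got {t!r}")
    out = np.empty_like(t_arr)
    flat_t = np.atleast_1d(t_arr)
    flat_o = np.atleast_1d(out)
    for i, ti in enumerate(flat_t):
        light = ti < cond.photoperiod_ext
        flat_o[i] = _kernels.beta_closed_form(
            ti, light, core.a, core.gamma, core.beta_p, core.kappa, cond.tau_L
        )
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


def ode_rhs(state, t: float, core: CoreParams, cond: ConditionParams,
            beta_fn=None):
    """Right-hand side (dC/dt, dS/dt) of the starch/sucrose ODEs.

    ``beta_fn`` overrides the closed-form degradation-rate profile (signature
    t -> rate); by default the homeostatic closed form is used. The
    degradation flux uses max(C, 0)**kappa so a zero starch pool contributes
    no flux.
    """
    C, S = float(state[0]), float(state[1])
    if C < 0 or S < 0:
        raise ValidationError(f"state must be non-negative, got C={C}, S={S}")
    light = (t % 1.0) < cond.photoperiod_ext
    if beta_fn is None:
        beta = _kernels.beta_closed_form(
            t % 1.0, light, core.a, core.gamma, core.beta_p, core.kappa, cond.tau_L
        )
    else:
        beta = float(beta_fn(t % 1.0))
    deg = beta * max(C, 0.0) ** core.kappa
    if light:
        return (core.a * core.gamma - deg,
                core.a * (1.0 - core.gamma) + deg - cond.H * S)
    return (-deg, deg - cond.H * S)


def homeostatic_initial_state(core: CoreParams, cond: ConditionParams):
    """Steady initial state (C0, S0) = (1/beta_p, a*tau_L/H).

    This is the state on the perfectly adjusted (homeostatic) orbit at dawn:
    residual starch 1/beta_p and constant sucrose a*tau_L/H.
    """
    if core.beta_p == 0 or cond.H == 0:
        raise ValidationError("beta_p and H must be nonzero")
    return 1.0 / core.beta_p, core.a * cond.tau_L / cond.H


def phase_step_counts(photoperiod_ext: float, steps_per_day: int,
                      tol: float = 1e-9):
    """Per-phase RK4 step counts for a steps_per_day grid.

    Raises ConfigurationError unless the grid divides both the light and the
    dark phase exactly, which is required so no step straddles the
    light/dark switch.
    """
    n_light = photoperiod_ext * steps_per_day
    if abs(n_light - round(n_light)) > tol * steps_per_day:
        raise ConfigurationError(
            f"steps_per_day={steps_per_day} does not divide the light phase "
            f"(photoperiod {photoperiod_ext}); choose a grid aligned with the "
            "light/dark switch"
        )
    n_light = int(round(n_light))
    if n_light == 0 or n_light == steps_per_day:
        raise ConfigurationError("grid leaves an empty light or dark phase")
    return n_light, steps_per_day - n_light


def simulate(theta: ThetaFull, cond: ConditionParams,
             n_days: int = DEFAULT_N_DAYS,
             dt: float = 1.0 / DEFAULT_STEPS_PER_DAY,
             initial_state=None) -> Trajectory:
    """Fixed-step RK4 trajectory over ``n_days`` diel cycles.

    ``dt`` (fraction of a day) must divide both phases; integration restarts
    at each light/dark switch. The initial state defaults to the homeostatic
    steady state. The degradation flux within a step is capped at C/dt so
    starch cannot be driven negative; a warning is logged when the cap binds.
    """
    if n_days < 1:
        raise ConfigurationError(f"n_days must be >= 1, got {n_days}")
    steps_per_day = 1.0 / dt
    if abs(steps_per_day - round(steps_per_day)) > 1e-9 * steps_per_day:
        raise ConfigurationError(f"1/dt must be an integer step count, got dt={dt}")
    steps_per_day = int(round(steps_per_day))
    n_light, n_dark = phase_step_counts(cond.photoperiod_ext, steps_per_day)
    core = theta.core
    if initial_state is None:
        C0, S0 = homeostatic_initial_state(core, cond)
    else:
        C0, S0 = float(initial_state[0]), float(initial_state[1])
        if C0 < 0 or S0 < 0:
            raise ValidationError("initial state must be non-negative")
    C, S, n_cap = _kernels.simulate_days(
        core.a, core.gamma, core.beta_p, core.kappa, cond.H, cond.tau_L,
        cond.photoperiod_ext, C0, S0, int(n_days), n_light, n_dark,
    )
    if not (np.all(np.isfinite(C)) and np.all(np.isfinite(S))):
        raise IntegrationError(
            "non-finite state during integration with "
            f"a={core.a}, gamma={core.gamma}, beta_p={core.beta_p}, "
            f"H={cond.H}, tau_L={cond.tau_L}"
        )
    if n_cap:
        logger.warning(
            "degradation flux cap bound on %d step(s); starch held at zero", n_cap
        )
    times = np.arange(n_days * steps_per_day + 1) * dt
    return Trajectory(times=times, C=C, S=S, condition=cond, n_capped_steps=n_cap)


def zt_to_step_index(zt_hours, steps_per_day: int) -> np.ndarray:
    """Map ZT hours in [0, 24] to step offsets within one simulated day."""
    zt = np.asarray(zt_hours, dtype=float)
    if np.any((zt < 0) | (zt > 24)):
        raise DomainError(f"ZT hours must lie in [0, 24], got {zt_hours!r}")
    idx = zt / 24.0 * steps_per_day
    if np.any(np.abs(idx - np.round(idx)) > 1e-9 * steps_per_day):
        raise ConfigurationError(
            f"sample times {zt_hours!r} do not fall on the {steps_per_day}-step "
            "daily grid"
        )
    return np.round(idx).astype(np.int64)


def predicted_profile(theta: ThetaFull, cond: ConditionParams, zt_hours,
                      n_days: int = DEFAULT_N_DAYS,
                      steps_per_day: int = DEFAULT_STEPS_PER_DAY):
    """Model means (C, S) at the requested ZT hours of the final simulated day.

    Simulates ``n_days`` from the homeostatic initial state and reads the
    last day, so transients from imperfect homeostasis have relaxed onto the
    periodic orbit; ZT 24 maps to the final point of the last day.
    """
    idx = zt_to_step_index(zt_hours, steps_per_day)
    n_light, n_dark = phase_step_counts(cond.photoperiod_ext, steps_per_day)
    core = theta.core
    muC, muS, n_cap = _kernels.mu_at_obs(
        core.a, core.gamma, core.beta_p, core.kappa, cond.H, cond.tau_L,
        cond.photoperiod_ext, int(n_days), n_light, n_dark, idx,
    )
    if not (np.all(np.isfinite(muC)) and np.all(np.isfinite(muS))):
        raise IntegrationError(
            "non-finite model means with "
            f"a={core.a}, beta_p={core.beta_p}, H={cond.H}, tau_L={cond.tau_L}"
        )
    return muC, muS
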