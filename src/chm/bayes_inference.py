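"""Bayesian fitting of the carbon-homeostasis model to paired LD+SD series.

The likelihood treats every scalar measurement (starch or sucrose at one ZT
in one condition) as an independent Normal observation around the model mean
mu_t, with separate variances for starch and sucrose. Model means come from
the RK4 solution evaluated on the final simulated day (the burn-in days let
the trajectory relax onto its periodic orbit). Priors are uniform: [0, 1]
for the ratio parameters (gamma and the subjective photoperiods) and bounded
positive intervals for the rates; the noise scales are sampled as standard
deviations under uniform priors and squared inside the likelihood.

Sampling uses an affine-invariant ensemble sampler (emcee) by default, with
walkers grouped into independent "chains" for R-hat/ESS reporting; a
self-contained adaptive random-walk Metropolis backend is provided as an
independent cross-check. Point estimates follow the kernel-density MAP
convention: a Gaussian KDE with Silverman bandwidth over the pooled draws,
evaluated on a 512-point grid.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .core_model import (
    FULL_PARAM_NAMES,
    LD_PHOTOPERIOD,
    PARAM_NAMES,
    SD_PHOTOPERIOD,
    ThetaFull,
    phase_step_counts,
    zt_to_step_index,
)
from .errors import ConfigurationError, ValidationError
from .synthetic_data import DielPair

logger = logging.getLogger(__name__)

RHAT_PASS = 1.01
RHAT_WARN = 1.05
ESS_FLOOR = 400.0


@dataclass(frozen=True)
class PriorSpec:
    """Independent uniform prior bounds per parameter (noise on the SD scale).

    Ratio parameters (gamma, tau_L_LD, tau_L_SD) are confined to [0, 1]; the
    rate parameters get generous positive ranges. Lower bounds on H and
    beta_p are kept slightly above zero because the homeostatic initial
    state contains 1/beta_p and a*tau_L/H.
    """

    bounds: dict = field(default_factory=lambda: {
        "a": (0.01, 30.0),
        "gamma": (0.0, 1.0),
        "H_LD": (0.05, 50.0),
        "tau_L_LD": (0.0, 1.0),
        "H_SD": (0.05, 50.0),
        "tau_L_SD": (0.0, 1.0),
        "beta_p": (0.05, 20.0),
        "sigma_c": (1e-3, 5.0),
        "sigma_s": (1e-3, 5.0),
    })

    def __post_init__(self) -> None:
        missing = set(FULL_PARAM_NAMES) - set(self.bounds)
        if missing:
            raise ValidationError(f"missing prior bounds for {sorted(missing)}")
        for name, (lo, hi) in self.bounds.items():
            if not lo < hi:
                raise ValidationError(f"prior for {name}: lower {lo} !< upper {hi}")
        for name in ("gamma", "tau_L_LD", "tau_L_SD"):
            lo, hi = self.bounds[name]
            if lo < 0.0 or hi > 1.0:
                raise ValidationError(f"ratio parameter {name} must stay in [0, 1]")

    def lower(self) -> np.ndarray:
        return np.array([self.bounds[n][0] for n in FULL_PARAM_NAMES])

    def upper(self) -> np.ndarray:
        return np.array([self.bounds[n][1] for n in FULL_PARAM_NAMES])

    def with_bounds(self, **updates) -> "PriorSpec":
        b = dict(self.bounds)
        for name, rng in updates.items():
            if name not in b:
                raise ValidationError(f"unknown parameter {name!r}")
            b[name] = tuple(rng)
        return PriorSpec(bounds=b)

    def in_support(self, x: np.ndarray) -> np.ndarray:
        """Boolean mask over rows of x (…, 9) inside the prior box."""
        lo, hi = self.lower(), self.upper()
        return np.all((x > lo) & (x < hi), axis=-1)

    def sample_central(self, rng: np.random.Generator, n: int) -> np.ndarray:
        """n draws from the central 50% of each prior range (initialization)."""
        lo, hi = self.lower(), self.upper()
        u = rng.uniform(0.25, 0.75, size=(n, len(lo)))
        return lo + u * (hi - lo)


@dataclass(frozen=True)
class SamplerConfig:
    """MCMC and solver settings for one fit."""

    chains: int = 4
    warmup: int = 1000
    samples: int = 1000
    walkers_per_chain: int = 6
    seed: int = 0
    backend: str = "emcee"
    steps_per_day: int = 96
    n_days: int = 6
    kappa: float = 2.0 / 3.0
    photoperiod_ld: float = LD_PHOTOPERIOD
    photoperiod_sd: float = SD_PHOTOPERIOD
    store_pointwise: bool = True
    pointwise_thin: int = 1

    def __post_init__(self) -> None:
        if self.chains < 2:
            raise ConfigurationError("need at least 2 chains for diagnostics")
        if self.warmup < 1 or self.samples < 1:
            raise ConfigurationError("warmup and samples must be >= 1")
        if self.backend not in ("emcee", "metropolis"):
            raise ConfigurationError(f"unknown backend {self.backend!r}")


@dataclass
class PosteriorDraws:
    """Post-warmup posterior draws plus convergence diagnostics.

    draws has shape (n_chains, n_draws_per_chain, n_params); for the
    ensemble backend each chain pools the walkers of one independent walker
    group. pointwise_loglik (n_total_draws_thinned, n_obs) is retained for
    WAIC.
    """

    draws: np.ndarray
    param_names: tuple
    n_chains: int
    n_warmup: int
    n_samples: int
    diagnostics: dict
    seed: int
    pointwise_loglik: np.ndarray | None = None

    def pooled(self) -> np.ndarray:
        return self.draws.reshape(-1, self.draws.shape[-1])

    def marginal(self, parameter: str) -> np.ndarray:
        if parameter not in self.param_names:
            raise ValidationError(f"unknown parameter {parameter!r}")
        return self.pooled()[:, self.param_names.index(parameter)]


@dataclass
class PosteriorSummary:
    """Per-parameter MAP / mean / sd / 95% HDI plus diagnostics."""

    map_estimate: dict
    mean: dict
    sd: dict
    hdi_95: dict
    diagnostics: dict

    def map_vector(self, names=PARAM_NAMES) -> np.ndarray:
        return np.array([self.map_estimate[n] for n in names])


class _PackedPair:
    """Observation arrays of one LD+SD pair laid out for the numba kernel."""

    def __init__(self, pair: DielPair, config: SamplerConfig):
        spd = config.steps_per_day
        self.nl_ld, self.nd_ld = phase_step_counts(config.photoperiod_ld, spd)
        self.nl_sd, self.nd_sd = phase_step_counts(config.photoperiod_sd, spd)
        self.idx_ld = zt_to_step_index(pair.ld.zt_hours, spd)
        self.idx_sd = zt_to_step_index(pair.sd.zt_hours, spd)
        self.obsC_ld = np.ascontiguousarray(pair.ld.starch)
        self.obsS_ld = np.ascontiguousarray(pair.ld.sucrose)
        self.obsC_sd = np.ascontiguousarray(pair.sd.starch)
        self.obsS_sd = np.ascontiguousarray(pair.sd.sucrose)
        self.config = config
        self.n_obs = 2 * len(self.idx_ld) + 2 * len(self.idx_sd)

    def pointwise(self, thetas: np.ndarray) -> np.ndarray:
        """Pointwise log-densities for rows of full 9-parameter vectors."""
        c = self.config
        return _kernels.loglik_pointwise_many(
            np.ascontiguousarray(thetas, dtype=float), c.kappa,
            c.photoperiod_ld, self.nl_ld, self.nd_ld, self.idx_ld,
            self.obsC_ld, self.obsS_ld,
            c.photoperiod_sd, self.nl_sd, self.nd_sd, self.idx_sd,
            self.obsC_sd, self.obsS_sd, c.n_days,
        )


def log_likelihood(theta: ThetaFull, pair: DielPair,
                   config: SamplerConfig | None = None):
    """Total and pointwise Gaussian log-likelihood of a paired series.

    The pointwise vector concatenates LD starch, LD sucrose, SD starch and
    SD sucrose blocks in sample-time order; its sum is the total.
    """
    if config is None:
        config = SamplerConfig()
    packed = _PackedPair(pair, config)
    pw = packed.pointwise(theta.full_vector()[None, :])[0]
    if not np.all(np.isfinite(pw)):
        logger.warning("non-finite pointwise log-likelihood; returning -inf")
        return -np.inf, pw
    return float(pw.sum()), pw


class _LogProb:
    """Vectorized flat-prior log-posterior over the 9-parameter box."""

    def __init__(self, packed: _PackedPair, priors: PriorSpec):
        self.packed = packed
        self.priors = priors

    def __call__(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(x)
        out = np.full(x.shape[0], -np.inf)
        ok = self.priors.in_support(x)
        if np.any(ok):
            pw = self.packed.pointwise(x[ok])
            tot = pw.sum(axis=1)
            tot[~np.isfinite(tot)] = -np.inf
            out[ok] = tot
        return out


def _diagnostics(walker_draws: np.ndarray, param_names) -> dict:
    """Max R-hat and min bulk ESS over parameters, walker-level chains."""
    import arviz as az

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ds = az.convert_to_dataset(walker_draws)  # (chain, draw, param)
        rhat = az.rhat(ds)
        ess = az.ess(ds)
    max_rhat = float(np.nanmax(rhat.to_array().values))
    min_ess = float(np.nanmin(ess.to_array().values))
    if max_rhat <= RHAT_PASS and min_ess >= ESS_FLOOR:
        status = "pass"
    elif max_rhat <= RHAT_WARN:
        status = "warn"
    else:
        status = "fail"
    return {"max_rhat": max_rhat, "min_ess": min_ess, "status": status}


def _heuristic_init(pair: DielPair, priors, config: SamplerConfig) -> np.ndarray:
    """Moment-based starting point for the 9-parameter fit.

    On the homeostatic orbit starch is piecewise linear with light slope
    a*(1-tau_L) and dark slope -a*tau_L, sucrose sits at a*tau_L/H, and dawn
    starch equals 1/beta_p; those relations invert the data into rough
    estimates. gamma is started at 1/2 (it only shapes off-orbit
    transients) and the noise SDs at a fraction of the data spread.
    """
    a_parts, taus, hs, bps = [], {}, {}, []
    for s, P_ext in ((pair.ld, config.photoperiod_ld),
                     (pair.sd, config.photoperiod_sd)):
        zt, C, S = s.zt_hours, s.starch, s.sucrose
        p_h = P_ext * 24.0
        light, dark = zt <= p_h, zt >= p_h
        slope_l = np.polyfit(zt[light] / 24.0, C[light], 1)[0]
        slope_d = np.polyfit(zt[dark] / 24.0, C[dark], 1)[0]
        a_c = max(slope_l - slope_d, 0.1)
        tau = float(np.clip(-slope_d / a_c, 0.02, 0.98))
        a_parts.append(a_c)
        taus[s.condition_label] = tau
        hs[s.condition_label] = a_c * tau / max(float(S.mean()), 1e-3)
        c_dawn = C[-1] if zt[-1] >= 24.0 - 1e-9 else C[0]
        bps.append(1.0 / max(float(c_dawn), 1e-2))
        sig_c = 0.2 * float(np.ptp(C)) + 1e-2
        sig_s = 0.2 * float(S.std() + 0.05 * S.mean()) + 1e-2
    x = np.array([float(np.mean(a_parts)), 0.5,
                  hs["LD"], taus["LD"], hs["SD"], taus["SD"],
                  float(np.mean(bps)), sig_c, sig_s])
    lo, hi = priors.lower(), priors.upper()
    margin = 0.01 * (hi - lo)
    return np.clip(x, lo + margin, hi - margin)


def _polish_start(log_prob, ndim, priors, config, rng, init_guess=None):
    """Locate a high-posterior start: short dispersed ensemble exploration,
    then Nelder-Mead polish of the best candidate (including the heuristic
    guess when provided)."""
    import emcee
    from scipy.optimize import minimize

    n_explore = max(2 * ndim + 2, 16)
    explorer = emcee.EnsembleSampler(n_explore, ndim, log_prob, vectorize=True)
    explorer.random_state = np.random.RandomState(
        rng.integers(0, 2**31 - 1)).get_state()
    explorer.run_mcmc(priors.sample_central(rng, n_explore),
                      max(50, config.warmup // 4), progress=False)
    flat = explorer.get_chain(flat=True)
    candidates = [flat[np.argmax(explorer.get_log_prob(flat=True))]]
    if init_guess is not None:
        candidates.append(np.asarray(init_guess, dtype=float))
    best_x, best_lp = None, -np.inf
    for x0 in candidates:
        if not np.isfinite(log_prob(x0[None, :])[0]):
            continue
        res = minimize(lambda x: -float(log_prob(x[None, :])[0]), x0,
                       method="Nelder-Mead",
                       options={"maxfev": 3000, "xatol": 1e-9, "fatol": 1e-9})
        if -res.fun > best_lp:
            best_x, best_lp = res.x, -res.fun
    if best_x is None:  # every candidate fell outside the support
        best_x = priors.sample_central(rng, 1)[0]
    return best_x


def _ball_init(center, priors, rng, n_walkers, ndim, rel_spread=1e-3):
    lo, hi = priors.lower(), priors.upper()
    spread = rel_spread * (hi - lo)
    p = np.empty((n_walkers, ndim))
    for w in range(n_walkers):
        while True:
            cand = center + spread * rng.standard_normal(ndim)
            if np.all((cand > lo) & (cand < hi)):
                p[w] = cand
                break
    return p


def _sample_emcee(log_prob, ndim, priors, config, rng,
                  init_guess=None) -> np.ndarray:
    import emcee

    n_walkers = config.chains * config.walkers_per_chain
    min_walkers = 2 * ndim + 2
    if n_walkers < min_walkers:
        # round the walker count up to the ensemble sampler's minimum,
        # keeping whole walker groups per reported chain
        wpc = int(np.ceil(min_walkers / config.chains))
        n_walkers = config.chains * wpc
    # The posterior mode is sharp relative to the flat prior box, so the
    # ensemble is started in a tight ball around an optimized point and the
    # warmup lets it decorrelate and spread to the posterior scale.
    start = _polish_start(log_prob, ndim, priors, config, rng, init_guess)
    p0 = _ball_init(start, priors, rng, n_walkers, ndim)
    # differential-evolution moves mix far better than the default stretch
    # move on this correlated posterior
    moves = [(emcee.moves.DEMove(), 0.8), (emcee.moves.DESnookerMove(), 0.2)]
    sampler = emcee.EnsembleSampler(n_walkers, ndim, log_prob, vectorize=True,
                                    moves=moves)
    sampler.random_state = np.random.RandomState(
        rng.integers(0, 2**31 - 1)).get_state()
    state = sampler.run_mcmc(p0, config.warmup, progress=False)
    sampler.reset()
    sampler.run_mcmc(state, config.samples, progress=False)
    chain = sampler.get_chain()  # (samples, n_walkers, ndim)
    logger.debug("emcee mean acceptance %.3f",
                 float(np.mean(sampler.acceptance_fraction)))
    return np.transpose(chain, (1, 0, 2))  # (walkers, samples, ndim)


def _sample_metropolis(log_prob, ndim, priors, config, rng,
                       init_guess=None) -> np.ndarray:
    """Adaptive random-walk Metropolis: independent chains, Haario-style
    covariance adaptation during warmup, frozen proposal afterwards."""
    n_chains = config.chains
    lo, hi = priors.lower(), priors.upper()
    start = _polish_start(log_prob, ndim, priors, config, rng, init_guess)
    out = np.empty((n_chains, config.samples, ndim))
    for c in range(n_chains):
        x = _ball_init(start, priors, rng, 1, ndim)[0]
        lp = float(log_prob(x[None, :])[0])
        scale = 2.38 / np.sqrt(ndim)
        # start the proposal at the init-ball scale; adaptation grows it to
        # the posterior scale during warmup
        chol = np.diag(1e-3 * (hi - lo))
        history = [x.copy()]
        n_acc_window = 0
        for it in range(config.warmup + config.samples):
            prop = x + scale * chol @ rng.standard_normal(ndim)
            lp_prop = float(log_prob(prop[None, :])[0])
            if np.log(rng.uniform()) < lp_prop - lp:
                x, lp = prop, lp_prop
                n_acc_window += 1
            if it < config.warmup:
                history.append(x.copy())
                if (it + 1) % 50 == 0:
                    scale *= np.exp(n_acc_window / 50.0 - 0.25)
                    n_acc_window = 0
                    recent = np.array(history[len(history) // 2:])
                    if len(recent) > 2 * ndim:
                        emp = np.cov(recent.T) + 1e-12 * np.diag((hi - lo) ** 2)
                        try:
                            chol = np.linalg.cholesky(emp)
                            scale = 2.38 / np.sqrt(ndim)
                        except np.linalg.LinAlgError:
                            pass
            else:
                out[c, it - config.warmup] = x
    return out


def sample_posterior(pair: DielPair, priors: PriorSpec | None = None,
                     config: SamplerConfig | None = None) -> PosteriorDraws:
    """Draw from the posterior over the 9 parameters for one LD+SD pair.

    Runs the configured backend, groups draws into ``config.chains`` chains,
    computes max R-hat / min ESS over post-warmup draws and stores pointwise
    log-likelihoods (thinned by ``config.pointwise_thin``) for WAIC.
    Non-convergence is flagged in ``diagnostics['status']``, not raised.
    """
    if priors is None:
        priors = PriorSpec()
    if config is None:
        config = SamplerConfig()
    packed = _PackedPair(pair, config)
    log_prob = _LogProb(packed, priors)
    rng = np.random.default_rng(config.seed)
    ndim = len(FULL_PARAM_NAMES)

    guess = _heuristic_init(pair, priors, config)
    if config.backend == "emcee":
        walker_draws = _sample_emcee(log_prob, ndim, priors, config, rng, guess)
    else:
        walker_draws = _sample_metropolis(log_prob, ndim, priors, config, rng,
                                          guess)

    if not np.all(np.isfinite(log_prob(walker_draws[:, -1, :]))):
        raise ValidationError(
            "chains ended outside the prior support; inspect the prior ranges"
        )
    diag = _diagnostics(walker_draws, FULL_PARAM_NAMES)
    if diag["status"] != "pass":
        logger.warning("convergence %s: max R-hat %.4f, min ESS %.0f",
                       diag["status"], diag["max_rhat"], diag["min_ess"])

    n_groups = config.chains
    wpg = walker_draws.shape[0] // n_groups
    draws = (walker_draws[: n_groups * wpg]
             .reshape(n_groups, wpg, -1, ndim)
             .transpose(0, 2, 1, 3)
             .reshape(n_groups, -1, ndim))

    pointwise = None
    if config.store_pointwise:
        pooled = draws.reshape(-1, ndim)[:: max(1, config.pointwise_thin)]
        pointwise = packed.pointwise(pooled)
    return PosteriorDraws(draws=draws, param_names=FULL_PARAM_NAMES,
                          n_chains=n_groups, n_warmup=config.warmup,
                          n_samples=draws.shape[1], diagnostics=diag,
                          seed=config.seed, pointwise_loglik=pointwise)


def map_estimate(draws, parameter: str | None = None) -> float:
    """Kernel-density MAP of one marginal posterior.

    Gaussian KDE with Silverman-rule bandwidth over the pooled chains,
    evaluated on a 512-point grid spanning the sampled range; returns the
    grid argmax. Accepts a PosteriorDraws plus parameter name, or a raw
    1-D sample array.
    """
    from scipy.stats import gaussian_kde

    if isinstance(draws, PosteriorDraws):
        x = draws.marginal(parameter)
    else:
        x = np.asarray(draws, dtype=float).ravel()
    if x.size < 100:
        raise ValidationError(f"need >= 100 draws for a KDE MAP, got {x.size}")
    if np.ptp(x) == 0.0:
        warnings.warn("degenerate (constant) sample; returning the common value")
        return float(x[0])
    kde = gaussian_kde(x, bw_method="silverman")
    grid = np.linspace(x.min(), x.max(), 512)
    return float(grid[np.argmax(kde(grid))])


def hdi_95(x: np.ndarray) -> tuple:
    import arviz as az

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        lo, hi = az.hdi(np.asarray(x, dtype=float).ravel(), hdi_prob=0.95)
    return float(lo), float(hi)


def summarize(draws: PosteriorDraws) -> PosteriorSummary:
    """Per-parameter MAP (KDE mode), mean, sd and 95% HDI."""
    maps, means, sds, hdis = {}, {}, {}, {}
    for name in draws.param_names:
        x = draws.marginal(name)
        maps[name] = map_estimate(x)
        means[name] = float(x.mean())
        sds[name] = float(x.std(ddof=1))
        hdis[name] = hdi_95(x)
    return PosteriorSummary(map_estimate=maps, mean=means, sd=sds,
                            hdi_95=hdis, diagnostics=dict(draws.diagnostics))


@dataclass
class BatchFit:
    """Result of one per-batch fit; failures carry error instead of draws."""

    batch: str
    draws: PosteriorDraws | None
    summary: PosteriorSummary | None
    error: str | None = None


def fit_batch_set(pairs: list, priors: PriorSpec | None = None,
                  config: SamplerConfig | None = None) -> list:
    """Independent posterior fits for a list of LD+SD pairs.

    Per-batch failures are isolated: the returned list always has one entry
    per input pair, with ``error`` set for failed fits.
    """
    if not pairs:
        raise ValidationError("need at least one paired dataset")
    if config is None:
        config = SamplerConfig()
    out = []
    for i, pair in enumerate(pairs):
        batch = getattr(pair, "batch", f"b{i + 1:02d}")
        try:
            cfg_i = SamplerConfig(**{**config.__dict__,
                                     "seed": config.seed + i})
            draws = sample_posterior(pair, priors, cfg_i)
            out.append(BatchFit(batch=batch, draws=draws,
                                summary=summarize(draws)))
        except Exception as exc:  # noqa: BLE001 - isolate per-batch failures
            logger.warning("fit failed for batch %s: %s", batch, exc)
            out.append(BatchFit(batch=batch, draws=None, summary=None,
                                error=str(exc)))
    return out
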