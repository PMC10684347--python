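"""Sparse mutant-deviation model selection by WAIC.

A mutant's parameter vector is modelled as theta_wt + Delta, where Delta is
zero in every component the genetic defect leaves untouched. Each of the
2^7 on/off patterns over (a, gamma, H_LD, tau_L_LD, H_SD, tau_L_SD, beta_p)
is a candidate model: flagged deviations are sampled with uniform priors on
the widest interval keeping theta_wt + Delta inside the parameter domain,
unflagged components are pinned at the wild-type point estimates, and the
mutant's noise variances are always re-estimated. Candidates are ranked by
the widely applicable information criterion,

    WAIC = -2 sum_i log( mean_j P(X_i | theta_j) )
           + 2 sum_i Var_j( log P(X_i | theta_j) ),

computed over the posterior draws theta_j with one scalar measurement as
the pointwise unit X_i; the lowest-WAIC model wins, ties going to the
sparser mask.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .bayes_inference import (
    PosteriorDraws,
    PriorSpec,
    SamplerConfig,
    _diagnostics,
    _PackedPair,
    _sample_emcee,
    _sample_metropolis,
    map_estimate,
)
from .core_model import PARAM_NAMES, ThetaFull
from .errors import ValidationError
from .synthetic_data import DielPair

logger = logging.getLogger(__name__)

N_PARAMS = len(PARAM_NAMES)


def enumerate_models(n_params: int = N_PARAMS) -> list:
    """All 2^n_params deviation masks in binary counting order.

    Mask k flags parameter j iff bit j of k is set, so the empty mask comes
    first and the full mask last; the order is deterministic and free of
    duplicates.
    """
    if n_params < 1:
        raise ValidationError(f"n_params must be >= 1, got {n_params}")
    return [tuple(bool((k >> j) & 1) for j in range(n_params))
            for k in range(2 ** n_params)]


def masks_over(param_names) -> list:
    """All full 7-bit masks whose flagged set ranges over a parameter subset.

    Useful for reduced enumerations when only some parameters are plausible
    deviation sites.
    """
    idx = []
    for name in param_names:
        if name not in PARAM_NAMES:
            raise ValidationError(f"unknown parameter {name!r}")
        idx.append(PARAM_NAMES.index(name))
    masks = []
    for sub in enumerate_models(len(idx)):
        full = [False] * N_PARAMS
        for j, flag in zip(idx, sub):
            full[j] = flag
        masks.append(tuple(full))
    return masks


@dataclass
class DeltaModel:
    """A sparse deviation from the wild-type parameter vector.

    mask flags which of the 7 parameters deviate; delta holds the deviation
    values (exactly 0 where unflagged); theta_wt_ref is the 7-vector of
    wild-type point estimates the deviations are anchored to.
    """

    mask: tuple
    delta: np.ndarray
    theta_wt_ref: np.ndarray

    def __post_init__(self) -> None:
        self.mask = tuple(bool(m) for m in self.mask)
        self.delta = np.asarray(self.delta, dtype=float)
        self.theta_wt_ref = np.asarray(self.theta_wt_ref, dtype=float)
        if len(self.mask) != N_PARAMS:
            raise ValidationError(f"mask must have {N_PARAMS} entries")
        if self.delta.shape != (N_PARAMS,) or self.theta_wt_ref.shape != (N_PARAMS,):
            raise ValidationError(f"delta and theta_wt_ref must be {N_PARAMS}-vectors")
        for j, flagged in enumerate(self.mask):
            if not flagged and self.delta[j] != 0.0:
                raise ValidationError(
                    f"unflagged component {PARAM_NAMES[j]} has nonzero delta"
                )

    @classmethod
    def zero(cls, theta_wt_ref) -> "DeltaModel":
        return cls(mask=(False,) * N_PARAMS, delta=np.zeros(N_PARAMS),
                   theta_wt_ref=theta_wt_ref)

    @classmethod
    def from_updates(cls, theta_wt_ref, **deltas) -> "DeltaModel":
        """Build a model from keyword deviations, e.g. beta_p=-0.75."""
        mask = [False] * N_PARAMS
        vec = np.zeros(N_PARAMS)
        for name, value in deltas.items():
            if name not in PARAM_NAMES:
                raise ValidationError(f"unknown parameter {name!r}")
            j = PARAM_NAMES.index(name)
            mask[j] = True
            vec[j] = float(value)
        return cls(mask=tuple(mask), delta=vec, theta_wt_ref=theta_wt_ref)

    def delta_vector(self) -> np.ndarray:
        return self.delta.copy()

    def theta_vector(self) -> np.ndarray:
        return self.theta_wt_ref + self.delta

    @property
    def n_flagged(self) -> int:
        return sum(self.mask)

    def mask_string(self) -> str:
        return "".join("1" if m else "0" for m in self.mask)


@dataclass
class WAICResult:
    """One fitted candidate model with its WAIC decomposition.

    waic = lppd_term + penalty_term; the penalty (effective-parameter) term
    is non-negative. model.delta carries the posterior MAP deviations.
    """

    model: DeltaModel
    waic: float
    lppd_term: float
    penalty_term: float
    fit: PosteriorDraws

    def param_draws(self, name: str) -> np.ndarray:
        """Pooled posterior draws of one of the 7 mutant parameters.

        Pinned parameters return a constant array at the wild-type anchor
        (a point mass).
        """
        if name not in PARAM_NAMES:
            raise ValidationError(f"unknown parameter {name!r}")
        j = PARAM_NAMES.index(name)
        n = self.fit.pooled().shape[0]
        base = self.model.theta_wt_ref[j]
        if not self.model.mask[j]:
            return np.full(n, base)
        return base + self.fit.marginal(f"delta_{name}")


def waic(pointwise_loglik: np.ndarray):
    """WAIC with its two terms from a (draws x observations) log-lik matrix.

    First term: -2 sum_i log-mean of exp(loglik) over draws, computed stably
    with log-sum-exp. Second term: +2 sum_i sample variance (ddof=1) of the
    log-lik over draws. Returns (waic, lppd_term, penalty_term).
    """
    ll = np.asarray(pointwise_loglik, dtype=float)
    if ll.ndim != 2:
        raise ValidationError("pointwise_loglik must be 2-D (draws x observations)")
    m, n = ll.shape
    if m < 2 or n < 1:
        raise ValidationError(f"need >= 2 draws and >= 1 observation, got {ll.shape}")
    if not np.all(np.isfinite(ll)):
        i, j = np.argwhere(~np.isfinite(ll))[0]
        raise ValidationError(
            f"non-finite log-likelihood at draw {i}, observation {j}"
        )
    lppd_term = -2.0 * float(np.sum(logsumexp(ll, axis=0) - np.log(m)))
    penalty_term = 2.0 * float(np.sum(np.var(ll, axis=0, ddof=1)))
    return lppd_term + penalty_term, lppd_term, penalty_term


class _DeltaBox:
    """Uniform box over the free coordinates of one deviation model:
    flagged deltas (bounded so theta_wt + delta stays in the domain) plus
    the two mutant noise SDs."""

    def __init__(self, mask, theta_wt: np.ndarray, priors: PriorSpec):
        lo_full = priors.lower()[:N_PARAMS]
        hi_full = priors.upper()[:N_PARAMS]
        lows, highs, names = [], [], []
        for j, flagged in enumerate(mask):
            if not flagged:
                continue
            lo, hi = lo_full[j] - theta_wt[j], hi_full[j] - theta_wt[j]
            if not lo < 0.0 < hi:
                raise ValidationError(
                    f"wild-type {PARAM_NAMES[j]}={theta_wt[j]:.4g} sits at the "
                    "domain edge; delta prior cannot bracket 0"
                )
            lows.append(lo)
            highs.append(hi)
            names.append(f"delta_{PARAM_NAMES[j]}")
        for s in ("sigma_c", "sigma_s"):
            lo, hi = priors.bounds[s]
            lows.append(lo)
            highs.append(hi)
            names.append(s)
        self._lo = np.array(lows)
        self._hi = np.array(highs)
        self.names = tuple(names)
        self.ndim = len(names)

    def lower(self) -> np.ndarray:
        return self._lo

    def upper(self) -> np.ndarray:
        return self._hi

    def in_support(self, x: np.ndarray) -> np.ndarray:
        return np.all((x > self._lo) & (x < self._hi), axis=-1)

    def sample_central(self, rng: np.random.Generator, n: int) -> np.ndarray:
        u = rng.uniform(0.25, 0.75, size=(n, self.ndim))
        return self._lo + u * (self._hi - self._lo)


class _DeltaLogProb:
    def __init__(self, packed: _PackedPair, box: _DeltaBox, mask,
                 theta_wt: np.ndarray):
        self.packed = packed
        self.box = box
        self.mask = np.array(mask, dtype=bool)
        self.theta_wt = theta_wt
        self.n_free = int(self.mask.sum())

    def full_thetas(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(x)
        thetas = np.tile(self.theta_wt, (x.shape[0], 1))
        thetas[:, self.mask] += x[:, : self.n_free]
        return np.hstack([thetas, x[:, self.n_free:]])

    def __call__(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(x)
        out = np.full(x.shape[0], -np.inf)
        ok = self.box.in_support(x)
        if np.any(ok):
            pw = self.packed.pointwise(self.full_thetas(x[ok]))
            tot = pw.sum(axis=1)
            tot[~np.isfinite(tot)] = -np.inf
            out[ok] = tot
        return out


def fit_delta_model(mask, pair_mutant: DielPair, theta_wt,
                    priors: PriorSpec | None = None,
                    config: SamplerConfig | None = None):
    """Fit one deviation model to mutant data; return (draws, WAICResult).

    ``theta_wt`` is a ThetaFull (its 7 model parameters are the anchor) or a
    bare 7-vector. Only flagged deviations and the mutant noise SDs are
    sampled; the empty mask fits the noise alone. The stored DeltaModel
    carries the KDE-MAP deviations.
    """
    if priors is None:
        priors = PriorSpec()
    if config is None:
        config = SamplerConfig()
    theta7 = (theta_wt.param_vector() if isinstance(theta_wt, ThetaFull)
              else np.asarray(theta_wt, dtype=float))
    if theta7.shape != (N_PARAMS,):
        raise ValidationError("theta_wt must supply 7 model parameters")
    mask = tuple(bool(m) for m in mask)
    if len(mask) != N_PARAMS:
        raise ValidationError(f"mask must have {N_PARAMS} entries")

    packed = _PackedPair(pair_mutant, config)
    box = _DeltaBox(mask, theta7, priors)
    log_prob = _DeltaLogProb(packed, box, mask, theta7)
    rng = np.random.default_rng(config.seed)

    # start the polish at zero deviation with mid-range noise SDs
    guess = np.concatenate([np.zeros(log_prob.n_free),
                            0.5 * (box.lower()[log_prob.n_free:]
                                   + box.upper()[log_prob.n_free:])])
    if config.backend == "emcee":
        walker_draws = _sample_emcee(log_prob, box.ndim, box, config, rng, guess)
    else:
        walker_draws = _sample_metropolis(log_prob, box.ndim, box, config, rng,
                                          guess)

    diag = _diagnostics(walker_draws, box.names)
    n_groups = config.chains
    wpg = walker_draws.shape[0] // n_groups
    grouped = (walker_draws[: n_groups * wpg]
               .reshape(n_groups, wpg, -1, box.ndim)
               .transpose(0, 2, 1, 3)
               .reshape(n_groups, -1, box.ndim))
    pooled = grouped.reshape(-1, box.ndim)[:: max(1, config.pointwise_thin)]
    pointwise = packed.pointwise(log_prob.full_thetas(pooled))
    draws = PosteriorDraws(draws=grouped, param_names=box.names,
                           n_chains=n_groups, n_warmup=config.warmup,
                           n_samples=grouped.shape[1], diagnostics=diag,
                           seed=config.seed, pointwise_loglik=pointwise)

    w, lppd, penalty = waic(pointwise)
    delta_map = np.zeros(N_PARAMS)
    for j, flagged in enumerate(mask):
        if flagged:
            delta_map[j] = map_estimate(draws.marginal(f"delta_{PARAM_NAMES[j]}"))
    model = DeltaModel(mask=mask, delta=delta_map, theta_wt_ref=theta7)
    return draws, WAICResult(model=model, waic=w, lppd_term=lppd,
                             penalty_term=penalty, fit=draws)


def select_model(results: list) -> WAICResult:
    """Lowest-WAIC entry; ties go to fewer flagged parameters, then to
    lexicographic mask order."""
    if not results:
        raise ValidationError("cannot select from an empty result list")
    return min(results, key=lambda r: (r.waic, r.model.n_flagged,
                                       tuple(int(m) for m in r.model.mask)))


@dataclass
class SelectionResult:
    """All candidate fits for one mutant plus the WAIC winner."""

    selected: WAICResult
    results: list = field(default_factory=list)

    def table(self):
        """Tidy ranking table: mask, waic, both terms, rank, selected flag."""
        import pandas as pd

        rows = sorted(self.results, key=lambda r: (r.waic, r.model.n_flagged))
        return pd.DataFrame({
            "mask": [r.model.mask_string() for r in rows],
            "waic": [r.waic for r in rows],
            "lppd_term": [r.lppd_term for r in rows],
            "penalty_term": [r.penalty_term for r in rows],
            "rank": np.arange(1, len(rows) + 1),
            "selected": [r is self.selected for r in rows],
        })


def run_selection(pair_mutant: DielPair, theta_wt,
                  priors: PriorSpec | None = None,
                  config: SamplerConfig | None = None,
                  masks=None) -> SelectionResult:
    """Fit every candidate mask (default: all 128) and select by WAIC."""
    if masks is None:
        masks = enumerate_models()
    results = []
    for k, mask in enumerate(masks):
        cfg = config if config is None else SamplerConfig(
            **{**config.__dict__, "seed": config.seed + 1000 + k})
        _, res = fit_delta_model(mask, pair_mutant, theta_wt, priors, cfg)
        results.append(res)
        logger.debug("mask %s WAIC %.2f", res.model.mask_string(), res.waic)
    return SelectionResult(selected=select_model(results), results=results)
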