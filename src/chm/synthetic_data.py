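"""Synthetic diel starch/sucrose datasets with the study's sampling design.

Emulates the measurement-level statistical structure the analysis assumes:
model-mean trajectories from the carbon-homeostasis ODEs, i.i.d. Gaussian
measurement noise with separate starch/sucrose variances, multiplicative
batch variation on photosynthesis (a) and sucrose consumption (H), and
mutants as sparse additive deviations from the wild-type parameter vector.

The default design mirrors the plant experiments: long days (16 h light)
sampled at ZT 0,1,2,4,8,12,15,16,20,23,24 and short days (8 h light) at
ZT 0,1,2,4,7,8,12,16,20,23,24, with 13 wild-type batches.
"""

from __future__ import annotations

import typing
from dataclasses import dataclass, field, replace

import numpy as np

from .core_model import (
    LD_PHOTOPERIOD,
    SD_PHOTOPERIOD,
    ConditionParams,
    CoreParams,
    ThetaFull,
    degradation_rate,
    predicted_profile,
)
from .errors import ValidationError

if typing.TYPE_CHECKING:  # pragma: no cover
    from .model_selection import DeltaModel

LD_ZTS = (0, 1, 2, 4, 8, 12, 15, 16, 20, 23, 24)
SD_ZTS = (0, 1, 2, 4, 7, 8, 12, 16, 20, 23, 24)


@dataclass
class DielSeries:
    """One genotype x condition x batch diel time series."""

    genotype: str
    batch: str
    condition_label: str
    zt_hours: np.ndarray
    starch: np.ndarray
    sucrose: np.ndarray
    maltose: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.zt_hours = np.asarray(self.zt_hours, dtype=float)
        self.starch = np.asarray(self.starch, dtype=float)
        self.sucrose = np.asarray(self.sucrose, dtype=float)
        if self.maltose is not None:
            self.maltose = np.asarray(self.maltose, dtype=float)
        if self.condition_label not in ("LD", "SD"):
            raise ValidationError(
                f"condition_label must be LD or SD, got {self.condition_label!r}"
            )
        if np.any(np.diff(self.zt_hours) <= 0):
            raise ValidationError("zt_hours must be strictly increasing")
        if np.any((self.zt_hours < 0) | (self.zt_hours > 24)):
            raise ValidationError("zt_hours must lie within [0, 24]")
        n = len(self.zt_hours)
        for name in ("starch", "sucrose", "maltose"):
            v = getattr(self, name)
            if v is None:
                continue
            if len(v) != n:
                raise ValidationError(f"{name} length {len(v)} != {n} sample times")
            if np.any(v < 0):
                raise ValidationError(f"{name} values must be non-negative")


@dataclass
class DielPair:
    """Paired LD + SD series for one genotype x batch; the unit of fitting."""

    ld: DielSeries
    sd: DielSeries

    def __post_init__(self) -> None:
        if self.ld.condition_label != "LD" or self.sd.condition_label != "SD":
            raise ValidationError("DielPair requires one LD and one SD series")
        if self.ld.genotype != self.sd.genotype:
            raise ValidationError("paired series must share a genotype")

    @property
    def genotype(self) -> str:
        return self.ld.genotype

    @property
    def batch(self) -> str:
        return self.ld.batch

    @property
    def n_obs(self) -> int:
        return 2 * (len(self.ld.zt_hours) + len(self.sd.zt_hours))


def pair_series(series: list[DielSeries]) -> list[DielPair]:
    """Group series into LD+SD pairs by (genotype, batch).

    Raises ValidationError for a (genotype, batch) group missing either
    condition or holding duplicates.
    """
    groups: dict[tuple[str, str], dict[str, DielSeries]] = {}
    for s in series:
        key = (s.genotype, s.batch)
        bucket = groups.setdefault(key, {})
        if s.condition_label in bucket:
            raise ValidationError(f"duplicate {s.condition_label} series for {key}")
        bucket[s.condition_label] = s
    pairs = []
    for key in sorted(groups):
        bucket = groups[key]
        if set(bucket) != {"LD", "SD"}:
            missing = {"LD", "SD"} - set(bucket)
            raise ValidationError(f"{key} is missing condition(s) {sorted(missing)}")
        pairs.append(DielPair(ld=bucket["LD"], sd=bucket["SD"]))
    return pairs


@dataclass(frozen=True)
class StudyDesign:
    """Sampling design: ZT grids, batch count and batch-level dispersion.

    batch_dispersion is the log-scale SD of the lognormal multiplicative
    factors applied per batch to a, H_LD and H_SD.
    """

    ld_zts: tuple = LD_ZTS
    sd_zts: tuple = SD_ZTS
    n_batches: int = 13
    batch_dispersion: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_batches < 1:
            raise ValidationError(f"n_batches must be >= 1, got {self.n_batches}")
        if self.batch_dispersion < 0:
            raise ValidationError("batch_dispersion must be >= 0")


def default_theta(sigma_c: float = 0.1, sigma_s: float = 0.05) -> ThetaFull:
    """Generating parameters used as the package's wild-type reference.

    Values are in the model's relative concentration units (day = 1):
    a = 6 fixes roughly 4x the dawn starch pool per day, gamma = 0.5 splits
    carbon evenly, the subjective photoperiods match the external ones
    (16 h LD, 8 h SD), sucrose turnover is faster under long days
    (H_LD = 4 > H_SD = 2 per day), and beta_p = 1 leaves a unit residual
    starch pool at dawn. The noise SDs are about 7% of the diel signal
    amplitude (starch spans about 1-2.3, sucrose about 1), the precision
    regime of replicate-pooled enzymatic assays in which the subjective
    photoperiod is identifiable from a single batch.
    """
    return ThetaFull(
        core=CoreParams(a=6.0, gamma=0.5, beta_p=1.0),
        ld=ConditionParams(H=4.0, tau_L=16.0 / 24.0,
                           photoperiod_ext=LD_PHOTOPERIOD, condition_label="LD"),
        sd=ConditionParams(H=2.0, tau_L=8.0 / 24.0,
                           photoperiod_ext=SD_PHOTOPERIOD, condition_label="SD"),
        sigma_c2=sigma_c ** 2,
        sigma_s2=sigma_s ** 2,
    )


def _noisy_series(theta: ThetaFull, cond: ConditionParams, zts, genotype: str,
                  batch: str, rng: np.random.Generator,
                  steps_per_day: int, n_days: int) -> DielSeries:
    zt = np.asarray(zts, dtype=float)
    muC, muS = predicted_profile(theta, cond, zt, n_days=n_days,
                                 steps_per_day=steps_per_day)
    starch = muC + rng.normal(0.0, np.sqrt(theta.sigma_c2), size=len(zt))
    sucrose = muS + rng.normal(0.0, np.sqrt(theta.sigma_s2), size=len(zt))
    # Gaussian noise can undershoot zero; observations are truncated at 0
    # (the likelihood stays plain Normal).
    return DielSeries(genotype=genotype, batch=batch,
                      condition_label=cond.condition_label, zt_hours=zt,
                      starch=np.maximum(starch, 0.0),
                      sucrose=np.maximum(sucrose, 0.0))


def generate_wildtype(theta: ThetaFull, design: StudyDesign,
                      genotype: str = "wildtype",
                      rng: np.random.Generator | None = None,
                      steps_per_day: int = 96,
                      n_days: int = 6) -> list[DielSeries]:
    """Wild-type diel datasets: one LD and one SD series per batch.

    Each batch multiplies (a, H_LD, H_SD) by independent lognormal factors
    with log-SD ``design.batch_dispersion``, then draws Gaussian measurement
    noise around the model means. Reproducible under ``design.seed`` (or an
    explicitly supplied generator).
    """
    if rng is None:
        rng = np.random.default_rng(design.seed)
    out: list[DielSeries] = []
    for b in range(design.n_batches):
        batch = f"b{b + 1:02d}"
        if design.batch_dispersion > 0:
            fa, fld, fsd = np.exp(rng.normal(0.0, design.batch_dispersion, size=3))
        else:
            fa = fld = fsd = 1.0
        theta_b = ThetaFull(
            core=replace(theta.core, a=theta.core.a * fa),
            ld=replace(theta.ld, H=theta.ld.H * fld),
            sd=replace(theta.sd, H=theta.sd.H * fsd),
            sigma_c2=theta.sigma_c2, sigma_s2=theta.sigma_s2,
        )
        out.append(_noisy_series(theta_b, theta_b.ld, design.ld_zts, genotype,
                                 batch, rng, steps_per_day, n_days))
        out.append(_noisy_series(theta_b, theta_b.sd, design.sd_zts, genotype,
                                 batch, rng, steps_per_day, n_days))
    return out


@dataclass
class MutantDataset:
    """Synthetic mutant data plus the generating truth, for recovery tests."""

    genotype: str
    series: list
    delta: "DeltaModel"
    theta_true: ThetaFull


def generate_mutant(theta_wt: ThetaFull, delta: "DeltaModel",
                    design: StudyDesign, genotype: str = "mutant",
                    rng: np.random.Generator | None = None,
                    steps_per_day: int = 96, n_days: int = 6) -> MutantDataset:
    """Mutant datasets from theta_mt = theta_wt + Delta.

    Delegates to generate_wildtype after validating that the shifted
    parameter vector stays inside its domain; the true mask and deviation
    are recorded alongside the data.
    """
    params_mt = theta_wt.param_vector() + delta.delta_vector()
    offending = _domain_violations(params_mt)
    if offending:
        raise ValidationError(
            "theta_wt + delta leaves the parameter domain for: "
            + ", ".join(offending)
        )
    theta_mt = theta_wt.with_params(params_mt)
    series = generate_wildtype(theta_mt, design, genotype=genotype, rng=rng,
                               steps_per_day=steps_per_day, n_days=n_days)
    return MutantDataset(genotype=genotype, series=series, delta=delta,
                         theta_true=theta_mt)


def _domain_violations(params: np.ndarray) -> list[str]:
    from .core_model import PARAM_NAMES

    bad = []
    for name, value in zip(PARAM_NAMES, params):
        if name in ("gamma", "tau_L_LD", "tau_L_SD"):
            if not 0.0 <= value <= 1.0:
                bad.append(f"{name}={value:.4g} outside [0, 1]")
        elif value <= 0.0:
            bad.append(f"{name}={value:.4g} not > 0")
    return bad


def generate_maltose(series: DielSeries, theta: ThetaFull, scale: float = 1.0,
                     noise_sd: float = 0.0,
                     rng: np.random.Generator | None = None,
                     steps_per_day: int = 96, n_days: int = 6) -> DielSeries:
    """Fill the maltose channel as scale * beta_t * C_t**kappa plus noise.

    Maltose is a starch-breakdown product produced at the granule surface, so
    its concentration tracks the degradation flux. beta_t and the
    model-consistent starch C_t are taken from the generating theta at the
    series' sample times; the dawn points (ZT 0 and 24) use the dark-side
    rate, since a ZT0 harvest precedes light onset.
    """
    if scale < 0:
        raise ValidationError(f"scale must be >= 0, got {scale}")
    if noise_sd < 0:
        raise ValidationError(f"noise_sd must be >= 0, got {noise_sd}")
    if rng is None:
        rng = np.random.default_rng(0)
    cond = theta.condition(series.condition_label)
    muC, _ = predicted_profile(theta, cond, series.zt_hours, n_days=n_days,
                               steps_per_day=steps_per_day)
    beta = _beta_at_zts(theta.core, cond, series.zt_hours)
    maltose = scale * beta * muC ** theta.core.kappa
    if noise_sd > 0:
        maltose = maltose + rng.normal(0.0, noise_sd, size=len(maltose))
    return DielSeries(genotype=series.genotype, batch=series.batch,
                      condition_label=series.condition_label,
                      zt_hours=series.zt_hours, starch=series.starch,
                      sucrose=series.sucrose,
                      maltose=np.maximum(maltose, 0.0))


def _beta_at_zts(core: CoreParams, cond: ConditionParams, zt_hours) -> np.ndarray:
    """beta_t at ZT hours with the dawn convention: ZT 0 and 24 take the
    dark-side (peak) limit."""
    zt = np.asarray(zt_hours, dtype=float)
    out = np.empty_like(zt)
    for i, z in enumerate(zt):
        if z <= 0.0 or z >= 24.0:
            # dark-side dawn limit t -> 1
            out[i] = core.a * cond.tau_L * core.beta_p ** core.kappa
        else:
            out[i] = degradation_rate(core, cond, z / 24.0)
    return out
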