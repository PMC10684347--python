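"""Empirical estimation of the diel starch-degradation-rate profile.

Maltose is the immediate product of starch breakdown at the granule
surface, so its concentration is proportional to the degradation flux
beta_t * C_t**kappa. Dividing maltose by the granule surface area
(starch**(2/3) for spherical granules) therefore recovers the degradation
rate up to an unknown proportionality constant:

    beta_hat_t = maltose_t / starch_t**kappa.

Because the scale is arbitrary, empirical and model-predicted profiles are
both standardized to a maximum of 1 before comparison; agreement is scored
by the mean absolute error over the shared ZT grid, alongside qualitative
trend checks (decreasing through the light phase, increasing through the
dark phase).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .core_model import ConditionParams, ThetaFull
from .errors import ValidationError
from .synthetic_data import _beta_at_zts

KAPPA_DEFAULT = 2.0 / 3.0


@dataclass
class BetaProfile:
    """A degradation-rate profile sampled at ZT hours (relative units).

    Undefined points (zero starch with nonzero maltose) are carried as NaN.
    """

    zt_hours: np.ndarray
    beta: np.ndarray
    standardized: bool = False
    source: str = "empirical"

    def __post_init__(self) -> None:
        self.zt_hours = np.asarray(self.zt_hours, dtype=float)
        self.beta = np.asarray(self.beta, dtype=float)
        if self.zt_hours.shape != self.beta.shape:
            raise ValidationError("zt_hours and beta must have equal length")
        if np.any(self.beta[np.isfinite(self.beta)] < 0):
            raise ValidationError("beta values must be non-negative")


def estimate_beta(maltose, starch, kappa: float = KAPPA_DEFAULT) -> BetaProfile:
    """Elementwise beta_hat = maltose / starch**kappa (unstandardized).

    Zero starch with zero maltose gives beta_hat = 0 (no granule, no flux);
    zero starch with positive maltose is an undefined rate - the point is
    masked as NaN and a warning is issued.
    """
    m = np.asarray(maltose, dtype=float)
    c = np.asarray(starch, dtype=float)
    if m.shape != c.shape:
        raise ValidationError("maltose and starch must have equal length")
    if np.any(m < 0) or np.any(c < 0):
        raise ValidationError("maltose and starch must be non-negative")
    beta = np.zeros_like(m)
    pos = c > 0
    beta[pos] = m[pos] / c[pos] ** kappa
    undefined = (~pos) & (m > 0)
    if np.any(undefined):
        warnings.warn(
            f"undefined degradation rate at {int(undefined.sum())} point(s) "
            "with zero starch but nonzero maltose; masking as NaN"
        )
        beta[undefined] = np.nan
    # raw-array input carries no sample times; use an index grid placeholder
    return BetaProfile(zt_hours=np.arange(len(m), dtype=float), beta=beta,
                       standardized=False, source="empirical")


def estimate_beta_series(series, kappa: float = KAPPA_DEFAULT) -> BetaProfile:
    """estimate_beta applied to a DielSeries carrying maltose, keeping its
    ZT grid."""
    if series.maltose is None:
        raise ValidationError("series has no maltose channel")
    prof = estimate_beta(series.maltose, series.starch, kappa=kappa)
    return replace(prof, zt_hours=series.zt_hours.copy())


def predicted_beta_profile(theta: ThetaFull, cond: ConditionParams,
                           zt_hours) -> BetaProfile:
    """Model-predicted beta_t at the given ZT grid (unstandardized).

    Dawn samples (ZT 0 and 24) take the dark-side peak value: a ZT0 harvest
    precedes light onset, so it sees the end-of-night rate.
    """
    beta = _beta_at_zts(theta.core, cond, zt_hours)
    return BetaProfile(zt_hours=np.asarray(zt_hours, dtype=float), beta=beta,
                       standardized=False, source="predicted")


def standardize_max1(profile: BetaProfile) -> BetaProfile:
    """Rescale so the maximum equals 1; idempotent, zero- and order-preserving."""
    finite = profile.beta[np.isfinite(profile.beta)]
    if finite.size == 0 or np.max(finite) <= 0:
        raise ValidationError("cannot standardize an all-zero profile")
    return replace(profile, beta=profile.beta / np.max(finite), standardized=True)


@dataclass
class ProfileComparison:
    """MAE between standardized profiles plus within-phase trend flags.

    light_decreasing / dark_increasing report the sign of the Spearman rank
    correlation of the empirical profile against time within each phase
    (None when no phase split was requested or a phase has < 2 points).
    """

    mae: float
    light_decreasing: bool | None = None
    dark_increasing: bool | None = None


def compare_profiles(empirical: BetaProfile, predicted: BetaProfile,
                     light_hours: float | None = None,
                     exclude_dawn: bool = False) -> ProfileComparison:
    """Mean absolute error between two standardized profiles on one grid.

    ``light_hours`` (the external photoperiod, in hours) enables the
    qualitative trend flags; ``exclude_dawn`` drops the ZT 0/24 samples from
    the MAE, where the discontinuity of beta_t makes the comparison
    convention-dependent. NaN (masked) points are excluded pairwise.
    """
    if not (empirical.standardized and predicted.standardized):
        raise ValidationError("both profiles must be standardized (max 1)")
    if (empirical.zt_hours.shape != predicted.zt_hours.shape
            or np.any(empirical.zt_hours != predicted.zt_hours)):
        raise ValidationError("profiles must share the same ZT grid")
    zt = empirical.zt_hours
    keep = np.isfinite(empirical.beta) & np.isfinite(predicted.beta)
    if exclude_dawn:
        keep &= (zt > 0) & (zt < 24)
    if not np.any(keep):
        raise ValidationError("no comparable points on the shared grid")
    mae = float(np.mean(np.abs(empirical.beta[keep] - predicted.beta[keep])))

    light_dec = dark_inc = None
    if light_hours is not None:
        from scipy.stats import spearmanr

        light = keep & (zt < light_hours)
        dark = keep & (zt >= light_hours)
        if light.sum() >= 2:
            rho = spearmanr(zt[light], empirical.beta[light]).statistic
            light_dec = bool(rho < 0)
        if dark.sum() >= 2:
            rho = spearmanr(zt[dark], empirical.beta[dark]).statistic
            dark_inc = bool(rho > 0)
    return ProfileComparison(mae=mae, light_decreasing=light_dec,
                             dark_increasing=dark_inc)
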