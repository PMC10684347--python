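# Methods notes

## Model

The carbon-homeostasis model tracks leaf starch `C_t` and sucrose `S_t`
through the diel cycle with time measured in days (dawn at t = 0, external
photoperiod `P` as a day fraction). In the light, photosynthesis fixes
carbon at rate `a`, a fraction `γ` goes to starch and `1−γ` to sucrose; at
all times starch is degraded into sucrose at flux `β_t·C^κ` and sucrose is
consumed/exported at rate `H·S`. The exponent `κ` reflects that degradation
enzymes act on the granule surface; we fix `κ = 2/3` (spherical granules)
but expose it in `CoreParams` since it is a shape property.

`β_t` is not free: it is the closed-form profile under which sucrose stays
constant at `S = a·τ_L/H` over the cycle (carbon homeostasis), parameterized
by the degradation potential `β_p` (dawn peak; dawn starch residue `1/β_p`)
and the subjective photoperiod `τ_L` (trough timing). On the homeostatic
orbit (`τ_L = P`) starch is piecewise linear with slopes `a(1−τ_L)` (light)
and `−a·τ_L` (dark) — these identities are the package's main analytic
oracles. When `τ_L < 1−γ` the light-phase numerator `a(γ−1+τ_L)` turns
negative; we clamp the light-phase rate to zero, the behaviour expected for
extremely short subjective photoperiods. The trigger `τ_L < 1−γ` is the
unique algebraic criterion consistent with the closed form. The dark-phase
profile is kept unchanged in that regime.

Convention: t = 0 is lights-on; light = [0, P), dark = [P, 1); the
dark-phase formula's `(1−t)` term makes dawn (t → 1) the peak. Sample times
are ZT hours (0–24) at the user surface; ZT 0 and ZT 24 are the dawn point
seen from the light and dark side respectively. For the degradation-rate
profile both dawn samples take the dark-side (peak) value, since a ZT0
harvest precedes light onset.

## Numerics

Integration is fixed-step classical RK4, restarted at the light/dark switch
so no step straddles the discontinuity; step counts must divide both phases
exactly (`ConfigurationError` otherwise). Dense simulation uses 1440
steps/day (1 simulated minute). Likelihood evaluations use 96 steps/day
(15-minute steps): against a 2880-step reference the final-day solution
agrees to < 3e-9 relative even for off-homeostasis parameters, far below
measurement noise, and the coarser grid makes the MCMC volume affordable.
Within a step the degradation flux is capped at `C/dt` so starch cannot be
driven negative; the cap binding is counted and logged. Trajectories start
from the homeostatic steady state `(C, S)(0) = (1/β_p, a·τ_L/H)` and run 6
days; model means are read on the final day, by which off-homeostasis
transients have relaxed onto the periodic orbit. (Reading days 4–6 instead
would triple identical likelihood terms once the orbit has converged, so
final-day evaluation is the default.)

## Likelihood and priors

Every scalar measurement (starch or sucrose, one ZT, one condition) is an
independent Normal observation around the model mean, with separate
variances for starch and sucrose; LD and SD observations carry equal
weight. Priors are independent uniforms: [0, 1] for the ratio parameters
(`γ`, `τ_L^LD`, `τ_L^SD`), bounded positive ranges for `a` (0.01–30),
`H` (0.05–50) and `β_p` (0.05–20) — the small lower bounds keep the initial
state `1/β_p`, `a·τ_L/H` finite — and the noise is sampled on the SD scale
(uniform 1e-3–5) and squared, which keeps the uniform-prior spirit with
better sampler geometry. All bounds are config-exposed.

## Sampling

The primary backend is the emcee affine-invariant ensemble with
differential-evolution moves (80% DE, 20% snooker), which mix much better
than stretch moves on this correlated 9-parameter posterior. The posterior
mode is extremely sharp relative to the prior box, and an ensemble started
from dispersed random draws does not contract onto it within a
1000-iteration warmup. Warmup therefore locates the mode first: a short
dispersed-ensemble exploration plus a moment-based initial guess (starch
slopes give `a` and `τ_L`, the sucrose level gives `H`, dawn starch gives
`β_p`), polished by Nelder–Mead; the walkers then start in a tight ball
(1e-3 of each prior range) around the optimum and decorrelate during the
remaining warmup. Walkers are grouped into `chains` (default 4) reporting
groups; R-hat and ESS are computed at walker granularity (max/min over
parameters) with thresholds R-hat ≤ 1.01 pass / ≤ 1.05 warn and an ESS
floor of 400; non-convergence is flagged, not fatal. A self-contained
adaptive random-walk Metropolis backend (Haario-style covariance adaptation
during warmup) serves as an independent cross-check; a test verifies the
two backends agree on posterior means within Monte-Carlo error.

Point estimates are kernel-density MAPs: Gaussian KDE with Silverman
bandwidth over the pooled draws, argmax on a 512-point grid spanning the
sampled range. 95% intervals are highest-density intervals.

## Mutant models, WAIC, effects

A mutant is `θ_wt + Δ` with `θ_wt` pinned at the wild-type MAP anchor (a
point, not a distribution; the anchor batch is configurable). Each of the
2⁷ masks over which components of `Δ` are nonzero is a candidate model;
flagged components get uniform priors on the widest interval keeping
`θ_wt + Δ` inside the parameter domain, and the mutant noise variances are
always re-estimated (noise is a property of the mutant's measurements).
Models are scored by WAIC with one scalar measurement as the pointwise
unit, computed stably by log-sum-exp, with sample variance (ddof = 1) in
the penalty; the lowest WAIC wins, ties to the sparser mask, then
lexicographic order. Reduced enumerations over a parameter subset
(`masks_over`) are available when only some parameters are plausible
deviation sites.

Effects: log2 fold changes of MAP estimates vs the wild-type anchor, with
|log2 FC| ≥ 1.5 (inclusive) flagged significant; parameters pinned by the
selected model have fold change exactly 0 by construction. Subjective
photoperiod shifts `Δτ_L` are distributions of `(τ_L^mut − τ_L^wt)·24 h`
over 10,000 independent resamples of the two posteriors (Monte-Carlo SE
well below 0.1 h); when the selected model pins `τ_L`, the mutant marginal
is a point mass at the anchor and every mutant still gets a `Δτ_L`. Both
the MAP and the mean of the difference distribution are reported; the MAP
is the headline number, consistent with the MAP convention elsewhere.

## Synthetic data

The generator emulates the measurement-level structure of the study design:
ZT grids {0,1,2,4,8,12,15,16,20,23,24} (LD, 16 h light) and
{0,1,2,4,7,8,12,16,20,23,24} (SD, 8 h light), 13 batches by default,
lognormal multiplicative batch factors on `a`, `H^LD`, `H^SD` (log-SD 0.1)
— batch differences are attributed to photosynthetic activity and sucrose
consumption — and i.i.d. Gaussian noise truncated at zero (the likelihood
ignores the truncation, matching the plain-Normal noise model; at the
default noise levels truncation is a far-tail event). Maltose, the
immediate product of granule-surface starch breakdown, is generated as
`scale·β_t·C_t^κ` plus optional noise, which the empirical estimator
`maltose/starch^(2/3)` inverts exactly in the noiseless case.

Wild-type generating values (`default_theta`): `a = 6`, `γ = 0.5`,
`H^LD = 4`, `H^SD = 2` (faster sucrose turnover under long days),
`β_p = 1`, `τ_L` equal to the external photoperiods (16 h / 8 h), noise
SDs 0.1 (starch) and 0.05 (sucrose) in the model's relative units. The
noise level is a deliberate calibration: it is ~7% of the diel signal
amplitude — the precision regime of replicate-pooled enzymatic assays —
and it places the subjective photoperiod in an identifiable regime
(single-batch posterior SD ≈ 0.4 h under LD, ≈ 0.7 h under SD). At twice
this noise the SD-condition dark starch slope no longer pins `a·τ_L^SD`
to better than ~1.4 h, and single-batch `τ_L` estimation degrades
accordingly; recovery tests report sensitivity through that lens rather
than assuming any particular assay precision. Note `γ = 0.5` puts the SD
condition in the clamped regime (`τ_L^SD = 1/3 < 1−γ`): generated SD
profiles have zero light-phase degradation, which is the model's expected
short-photoperiod behaviour.

What the generator does *not* emulate: developmental-stage differences,
irradiance differences between conditions, non-Gaussian or
heteroscedastic assay errors, circadian gene expression, or
batch-dependent `τ_L`. Passing recovery tests therefore demonstrate the
estimator works when the model is well-specified at realistic noise; they
do not validate the model against real plants.

## Scaled-down experiment sizes

The verification experiments (test suite and `scripts/acceptance.py`) use
sizes chosen to run comfortably on a single CPU: parameter recovery uses
20 single-batch datasets at the study's per-batch sample size (44 scalar
observations) with 4×(500+500) MCMC; sparsity recovery uses 10 mutants
with one large injected deviation (`β_p/4` or `τ_L^LD − 2 h`) and a
16-model enumeration over (`a`, `H^LD`, `τ_L^LD`, `β_p`) at 4×(250+250);
the full 128-model enumeration at default settings is the long-running
mode driven through `chm select`.

## Known limitations

- The posterior can be multimodal for noisy single batches; the
  mode-seeking warmup samples the dominant basin and the reported
  diagnostics should be checked before trusting a fit.
- WAIC with ~2000 retained draws has Monte-Carlo noise of a few units;
  near-ties between nested masks are resolved by the sparsity tie-break
  and can flip between seeds.
- The Normal likelihood ignores the zero-truncation of concentrations,
  acceptable at the default noise levels but biased if noise SDs approach
  the signal mean.
- `Δτ_L` resampling treats the wild-type anchor batch as exchangeable with
  the mutant's growth batch; systematic batch effects fold into the
  estimated deviation.
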