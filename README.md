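# chm — carbon-homeostasis modelling of diel starch metabolism

`chm` is an analysis pipeline for quantifying how genetic defects perturb
transitory starch metabolism in plant leaves. Plants fix carbon only in the
light, store part of it as starch, and degrade that starch overnight at a
clock-gated rate tuned so that sucrose — the transport sugar — stays nearly
constant across the day/night cycle (*carbon homeostasis*). The pipeline
fits a compact dynamical model of this process to diel starch/sucrose time
series, selects sparse mutant-vs-wild-type difference models, and turns the
fits into interpretable effect sizes. It is aimed at quantitative plant
biologists analysing diel metabolite profiles of wild-type and mutant
*Arabidopsis*-style experiments.

## The model

Starch `C_t` and sucrose `S_t` evolve under light/dark-switched ODEs (time
in days, day = 1, dawn at t = 0, external photoperiod `P`):

```
dC/dt =  a·γ − β_t·C^κ              (light)        −β_t·C^κ              (dark)
dS/dt =  a·(1−γ) + β_t·C^κ − H·S    (light)        β_t·C^κ − H·S         (dark)
```

with photosynthesis rate `a`, starch partitioning fraction `γ`, sucrose
consumption/export rate `H`, and granule-surface exponent `κ = 2/3`
(degradation acts on the surface of spherical granules). The degradation
rate `β_t` is the closed-form profile that realizes sucrose homeostasis:

```
β_t = a(γ−1+τ_L)·β_p^κ / (a·β_p·(1−τ_L)·t + 1)^κ     (light)
β_t = a·τ_L·β_p^κ / (a·β_p·τ_L·(1−t) + 1)^κ          (dark)
```

It peaks at dawn; `β_p` (degradation potential) sets the peak and the dawn
starch residue `1/β_p`; the *subjective photoperiod* `τ_L` sets the trough
timing and equals the external photoperiod when degradation is perfectly
adjusted. When `τ_L < 1−γ` the light-phase rate is clamped to zero
(extremely short subjective photoperiod). Deviations of `τ_L` from the
external photoperiod — and mutant−wild-type shifts `Δτ_L` — measure how
well a genotype synchronizes starch degradation to its light environment.

The seven inferred parameters are `θ = (a, γ, H^LD, τ_L^LD, H^SD, τ_L^SD,
β_p)` plus starch/sucrose noise variances. Fitting is Bayesian: a Normal
likelihood around the RK4-integrated model means, uniform priors, ensemble
MCMC (4 chains × 1000 warmup + 1000 kept draws by default), kernel-density
MAP point estimates, R-hat/ESS diagnostics. Mutants are modelled as
`θ_wt + Δ` with a sparse `Δ`; all 2⁷ = 128 sparsity patterns are candidate
models ranked by WAIC. Selected models yield per-parameter log2 fold
changes (|log2 FC| ≥ 1.5 flagged significant) and posterior-resampled
`Δτ_L` distributions in hours. A separate module estimates `β_t`
empirically as maltose/starch^(2/3) and scores it against the model
prediction by MAE after max-1 standardization.

A synthetic-data generator reproduces the study design (LD 16 h light
sampled at ZT 0,1,2,4,8,12,15,16,20,23,24; SD 8 h light at ZT
0,1,2,4,7,8,12,16,20,23,24; 13 batches; lognormal batch variation on `a`
and `H`; Gaussian measurement noise), so the whole pipeline is testable
without any external data.

## Worked example

```python
import numpy as np
import chm

theta = chm.default_theta()                      # wild-type reference
design = chm.StudyDesign(n_batches=1, batch_dispersion=0.0, seed=3)
pair = chm.pair_series(chm.generate_wildtype(theta, design))[0]

cfg = chm.SamplerConfig(chains=4, warmup=500, samples=500, seed=5)
draws = chm.sample_posterior(pair, chm.PriorSpec(), cfg)
summ = chm.summarize(draws)
for name in ("tau_L_LD", "tau_L_SD", "beta_p"):
    lo, hi = summ.hdi_95[name]
    print(f"{name}: MAP {summ.map_estimate[name]:.3f} "
          f"(95% HDI {lo:.3f}-{hi:.3f})")
```

prints (generating values: `tau_L_LD` = 16 h/24 ≈ 0.667, `tau_L_SD` =
8 h/24 ≈ 0.333, `beta_p` = 1):

```
tau_L_LD: MAP 0.679 (95% HDI 0.639-0.718)
tau_L_SD: MAP 0.346 (95% HDI 0.290-0.440)
beta_p: MAP 0.907 (95% HDI 0.711-1.182)
```

i.e. both subjective photoperiods are recovered within ~0.3 h of the truth
and the dawn degradation potential within its posterior uncertainty.
Multiply `tau_L` by 24 for hours. (A convergence warning at these reduced
sampler settings is expected; the default 1000+1000 iterations tighten the
diagnostics.)

The same stages are scriptable from the shell:

```bash
chm simulate --config config.yaml --seed 1 --out run1   # synthetic data CSV
chm fit      --config config.yaml --out run1            # wild-type posterior
chm select   --config config.yaml --out run1            # WAIC model selection
chm assess   --config config.yaml --out run1            # effects table
chm beta     --config config.yaml --out run1            # empirical beta_t
chm verify   --out run1                                 # re-check config hashes
```

## Layout

- `src/chm/core_model.py` — ODEs, closed-form `β_t`, RK4 simulation
- `src/chm/synthetic_data.py` — study-design data generator (wild type, mutants, maltose)
- `src/chm/bayes_inference.py` — likelihood, priors, MCMC backends, MAP/HDI summaries
- `src/chm/model_selection.py` — `Δ`-model enumeration, WAIC, selection
- `src/chm/mutant_effects.py` — log2 fold changes, `Δτ_L` distributions
- `src/chm/beta_empirical.py` — maltose-based `β_t` estimation and comparison
- `src/chm/cli_io.py`, `src/chm/cli.py` — tidy CSV/YAML/JSON I/O and the `chm` CLI
- `docs/methods.md` — modelling and inference notes
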