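# seasonhmm

Bayesian two-state hidden Markov movement models (HMMs) with
penalized-spline seasonal transition probabilities, for daily GPS telemetry
from collared animals.

Movement ecologists often want to know *when* animals switch between
localized movements and long-distance movements over the year — migration
onsets, facultative winter movements, spring returns — without forcing each
animal into an a priori movement class. `seasonhmm` addresses this with a
population-level HMM over daily step lengths and turning angles: a
short-distance local movement state (SDLM) and a long-distance movement
state (LDM), with state-transition probabilities that vary smoothly over a
biological year (July 1 – June 30). The package covers the full pipeline —
GPS fix preprocessing, likelihood, MCMC estimation, convergence diagnostics,
and post hoc seasonal summaries — plus a synthetic track generator so every
stage can be exercised and validated without telemetry data.

## Model

For day *t* of the biological year, latent states evolve through

```
Γ_t = | 1 − γ12(t)    γ12(t)   |        logit γij(t) = β⁰ij + Σₖ bijₖ Z[t, k]
      |   γ21(t)    1 − γ21(t) |        bijₖ ~ Normal(0, σi)
```

where Z is a K = 5 low-rank radial spline basis with knots evenly spaced on
[1, 365]. Conditional on the state *i*,

```
step   | state = i ~ Gamma(αi, βi)          (parameterized by mean mᵢ, sd σᵢ)
turn   | state = i ~ wrapped Cauchy(μi, ρi)
```

with the label constraint m₂ = m₁ + δ, δ > 0 (state 2 takes longer steps),
which removes label switching. States are marginalized with the forward
algorithm in log space; missing steps/turns (fix gaps) are marginalized out
while the transition across the gap still applies. Inference is MCMC
(blocked adaptive random-walk Metropolis) under the priors documented in
`docs/methods.md`; posteriors are summarized by medians and 90% highest
posterior density intervals (HPDI), convergence by split-chain Gelman–Rubin
factors. A post hoc pass propagates the state distribution through the year
(Chapman–Kolmogorov) to get the daily marginal probability of being in the
LDM state, and reads seasonal event days (fall/spring movement start and
end) off that curve's first derivative.

## Worked example

Simulate a deer-like scenario (strongly seasonal migrant: fall and spring
movement pulses, step means 0.66 vs 7.12 km, 8% missing data) and re-fit it:

```python
import numpy as np
from seasonhmm import (build_basis, make_knots, preset_scenario, simulate_dataset,
                       StackedSeries, SamplerConfig, sample_posterior,
                       summarize_posterior)
from seasonhmm.inference import convergence_diagnostics
from seasonhmm.seasonal import posterior_marginal_curve

basis = build_basis(make_knots(5, 1, 365))
scenario = preset_scenario("deer_like", basis, n_animal_years=20)
sims = simulate_dataset(scenario, seed=42)
data = StackedSeries([s.series for s in sims])

config = SamplerConfig(n_chains=3, n_iter=4000, n_burn=2000, thin=5, seed=0)
samples = sample_posterior(data, config=config, basis=basis)

table = summarize_posterior(samples)
print(table.loc[["mu1_step", "mu2_step", "sd_step[1]", "sd_step[2]",
                 "rho_turn[1]", "rho_turn[2]",
                 "cos_mu_turn[1]", "cos_mu_turn[2]"]].round(3))
print(f"\nmax split-Rhat: {convergence_diagnostics(samples).max():.3f}")

curve, timing, _ = posterior_marginal_curve(samples, basis)
print(timing.to_frame().round(1).to_string(index=False))
```

Output:

```
                median  hpdi_lo  hpdi_hi
parameter
mu1_step         0.671    0.657    0.685
mu2_step         6.999    6.637    7.292
sd_step[1]       0.583    0.569    0.599
sd_step[2]       6.639    6.306    7.016
rho_turn[1]      0.276    0.261    0.291
rho_turn[2]      0.697    0.680    0.715
cos_mu_turn[1]  -1.000   -1.000   -0.998
cos_mu_turn[2]   1.000    0.999    1.000

max split-Rhat: 1.040
       event  median_day  hpdi_lo  hpdi_hi  fraction_undefined
  fall_start        80.0     73.0     86.0                 0.0
    fall_end       140.0    132.0    146.0                 0.0
spring_start       245.0    241.0    250.0                 0.0
  spring_end       318.0    311.0    323.0                 0.0
```

The generative truth (m₁ = 0.66 km, m₂ = 7.12 km, σ = 0.57/6.49 km,
ρ = 0.26/0.70) falls inside the 90% intervals; the SDLM mean turning angle
is π (course reversals, cos μ₁ = −1) and the LDM state moves directionally
(cos μ₂ = +1). All split-R̂ values are below the 1.1 convergence threshold.
The event table gives the posterior timing of the fall and spring
long-distance movement periods: the days on which the marginal LDM
probability rises and falls fastest.

Real collar data enters the same way via the preprocessing chain:

```python
from seasonhmm import read_fixes_csv, process_fixes
series, rejected = process_fixes(read_fixes_csv("fixes.csv"))  # per animal-year
data = StackedSeries([s for s in series])
```

A small CLI mirrors the generator:
`seasonhmm simulate --scenario pronghorn_like -n 25 --seed 7 --outdir out/`
writes raw 2-hourly fixes, daily series, and true-state tables as CSV.

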