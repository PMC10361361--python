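# Methods

## Model

`seasonhmm` fits a population-level, two-state hidden Markov movement model
(HMM) to daily step lengths and turning angles from GPS-collared animals.
State 1 is a short-distance local movement state (SDLM) and state 2 a
long-distance movement state (LDM). Two stochastic processes define the
model: a time-inhomogeneous Markov chain over the latent states, and a
state-conditional movement process.

**State process.** Transitions from day *t−1* to day *t* follow a 2×2
stochastic matrix

Γ_t = [[1−γ₁₂(t), γ₁₂(t)], [γ₂₁(t), 1−γ₂₁(t)]],

with logit-linear off-diagonals

logit γᵢⱼ(t) = β⁰ᵢⱼ + fᵢⱼ(day of year),  i ≠ j,

where the day of year runs over a biological year (July 1 = day 1,
June 30 = day 365). The seasonal effect fᵢⱼ is a penalized spline in its
random-effects formulation: fᵢⱼ(d) = Σₖ bᵢⱼₖ Z[d, k] with K = 5 knots evenly
spaced on [1, 365] and bᵢⱼₖ ~ Normal(0, σᵢ). The basis is deliberately
non-cyclic (July-to-July continuity is not enforced), so end-of-year and
start-of-year probabilities may differ slightly.

**Movement process.** Conditional on the state, steps are gamma and turns
wrapped Cauchy:

step | state=i ~ Gamma(αᵢ, βᵢ),  turn | state=i ~ wrapped Cauchy(μᵢ, ρᵢ),

with the gamma parameterized through its mean mᵢ and standard deviation σᵢ
(αᵢ = mᵢ²/σᵢ², βᵢ = mᵢ/σᵢ²), which is much better behaved under MCMC than
shape/rate. The label constraint m₂ = m₁ + δ with δ > 0 defines state 2 as
the larger-step state and removes label switching structurally rather than
by post hoc relabeling.

**Initial states.** Each unique day that begins an animal record gets its
own initial-state distribution φ_t with a flat Dirichlet(1, 1) prior.

**Likelihood.** Animal-years are treated as independent series and
completely pooled (shared parameters, no individual or year effects). The
latent states are marginalized with the forward algorithm, computed in log
space with per-step rescaling (a 365-day product underflows otherwise). A
missing step or turn contributes a unit emission factor — i.e. it is
marginalized out — while the transition across the gap still applies. The
transition matrix applied on the step into day *t* is Γ evaluated at day
*t*; the alternative convention Γ(t−1) differs only by a one-day phase
shift of the seasonal curves, and the choice is fixed and documented here.

## Spline basis

The working basis is the low-rank radial (thin-plate-style) construction:
Z_raw[d, k] = |d − κₖ|³, Ω[k, k′] = |κₖ − κₖ′|³, Z = Z_raw Ω^(−1/2), so that
iid normal coefficients induce the usual thin-plate smoothness penalty. The
cubic radial Gram matrix Ω is only conditionally positive definite (its
eigenvalues have both signs for these knots), so the symmetric square root
is taken through the SVD, U √s Vᵀ — the convention of the penalized-spline
literature; the inverse square root exactly inverts it, and the round trip
Z · Ω^(1/2) = Z_raw holds to floating-point precision. Columns of Z are then
rescaled to unit sample standard deviation: raw cubic magnitudes reach 10⁷
over a 365-day domain, which would couple the prior scale of σᵢ to an
arbitrary basis normalization. The rescaling only reparameterizes b; the
curve family is unchanged. A cubic B-spline basis is available as a plug-in
alternative (`build_basis(..., kind="bspline")`); all downstream code is
basis-agnostic and the `formulation_tag` records which construction was
used.

## Preprocessing

Raw fixes are grouped per animal and biological year, deduplicated, and
resampled to one fix per calendar day — the fix closest in time to 06:00,
with ties going to the earlier fix. Steps are distances (km) between
consecutive daily fixes; the turn on day *t* is the deviation of the
*t−1 → t* bearing from the *t−2 → t−1* bearing, counterclockwise positive,
wrapped to (−π, π]. Any quantity spanning an unobserved day is flagged
missing, and the daily grid is kept complete. Leap days share Feb 28's index
so every year is 1..365. Animal-years with fewer than three daily fixes are
rejected with a diagnostic. Steps under 1 m are floored at 1 m so the gamma
density stays finite; sub-millimeter GPS steps do not occur in practice and
observed minima in this kind of data are of order tens of meters.

Coordinates are planar meters (projected CRS) by default. A geodesic mode
(spherical great-circle distances and forward azimuths) handles lon/lat
input; neither mode is asserted to be "the" convention of any particular
study, since published workflows use both. 06:00 is interpreted in the
timestamps' own clock; inputs must share a single local time zone.

## Priors and sampling

Priors: half-Normal(10) on m₁, δ, σ₁, σ₂ and the spline random-effect sds;
Uniform(−π, π) and Uniform(0, 1) on turning-angle means and concentrations;
Normal(0, 2) on the logit intercepts; Normal(0, σᵢ) hierarchically on the
spline coefficients; Dirichlet(1, 1) on each φ_t.

The sampler is a blocked adaptive random-walk Metropolis on the
marginalized likelihood. Blocks: the four step parameters (log scale); one
(μ, ρ) pair per state for the turning angles (means unbounded with wrapping
at the parameter map, ρ on the logit scale) — per-state pairs, because with
overlapping step distributions the joint turn posterior is non-Gaussian and
a single 4-dim covariance mixes the tight and diffuse coordinates badly;
each transition curve (intercept + 5 coefficients); the random-effect sds
(log scale; prior-only conditional); and one scalar update per record-start
φ (logit scale) that recomputes only the affected series' likelihood terms.
Each block uses Haario-style empirical-covariance proposals with
Robbins–Monro scale adaptation targeting 0.3 (0.44 for scalars); adaptation
runs during burn-in only, so the post-burn-in kernel is a fixed, valid
Metropolis kernel. Three devices matter for mixing and are pure bijections
or proposal choices with no effect on the posterior:

- the transition blocks are proposed in QR-preconditioned coordinates
  (design X = [1 | Z] = QR, working vector w = R·(β⁰, b)), making the
  likelihood curvature nearly isotropic in the block;
- their proposal covariance is seeded with a Laplace (inverse-Hessian,
  central-difference) estimate at the starting point, carried as
  pseudo-observations that the empirical adaptation then refines — these
  blocks mix tightly identified and prior-dominated directions whose scales
  differ by orders of magnitude;
- turning-angle means are proposed on the unbounded line and wrapped only
  when mapped to natural parameters, so a posterior concentrated at ±π does
  not produce artificial jumps.

Initial values come from a two-component moment split of the pooled steps at
their 75th percentile (per-state means/sds, and per-state circular moments
of the turns on low-step vs high-step days), which avoids label-flipped
starts; b = 0, φ = (0.5, 0.5), plus per-chain jitter. A non-finite starting
posterior is retried with growing jitter up to 20 times.

The full protocol is 3 chains × 20,000 iterations, 10,000 burn-in, thinned
by 5 (6,000 retained draws). Convergence is summarized by the split-chain
potential scale reduction factor with threshold 1.1; for the circular
turning-angle means the PSRF is computed on the cos/sin embedding, because
the statistic on a raw wrapped angle is meaningless when the posterior
straddles ±π (as it does for the SDLM state, whose mean direction is π).
Posteriors are summarized by the median and the 90% highest posterior
density interval (narrowest contiguous window on sorted draws; ties go to
the lowest start). Turning-angle means are additionally reported as
(cos μ, sin μ) pairs.

## Seasonal summaries

The marginal probability of being in the LDM state on day *t* is obtained by
propagating a day-1 state distribution through the daily transition matrices
(Chapman–Kolmogorov). The anchor is the estimated φ for day 1 if a record
starts on day 1, else (0.5, 0.5) — the simplest rule that combines the
estimated record-start distributions with the transition process. The
choice is recorded in the curve metadata; its influence decays geometrically
within a few weeks at typical transition probabilities.

Seasonal events are read off the first derivative of that curve (centered
differences, one-sided at the ends, after a 7-day centered moving average):
scanning from day 1, fall start = first local maximum, fall end = first
subsequent local minimum, spring start = second maximum, spring end = second
minimum. Extrema must clear a prominence floor of 0.005/day so that
Monte-Carlo wiggle in per-draw curves does not spawn spurious events; both
the window and the floor are configurable and logged. Events are computed
per posterior draw and then summarized (median, 90% HPDI, fraction of draws
where the event is undefined), which propagates posterior uncertainty into
the event days; computing events once on the posterior-median curve is
available as an option.

## Synthetic data

The generator draws states from the day-specific transition matrices and
observations from the state-conditional distributions — exactly the
structure the model assumes — so parameter recovery is well-defined. Two
presets encode the qualitative contrast between a strongly seasonal migrant
and a facultative mover:

- `deer_like`: m = (0.66, 7.12) km, sd = (0.57, 6.49) km, μ = (π, 0),
  ρ = (0.26, 0.70); bimodal SDLM→LDM curve (fall and spring pulses, winter
  trough), high LDM→SDLM return outside the pulses; 8% missing steps.
- `pronghorn_like`: m = (1.17, 3.64) km, sd = (0.947, 3.04) km, μ = (π, 0),
  ρ = (0.24, 0.12); single early-winter SDLM→LDM peak (near day 150),
  uniformly low return probability; 0.5% missing steps.

Emission values sit near published point estimates for the corresponding
species; seasonal truth curves are specified as probability-scale control
points, interpolated monotonically on the logit scale, and projected by
least squares onto the working basis. The projected curve — not the
hand-drawn one — is the recorded truth, keeping truth inside the model
family; control-point peaks are exaggerated because the smooth K = 5 basis
damps them. Start days are uniform on days 1–30 (records begin near
July 1); every series runs to day 365. Missing fixes arrive in runs: an
on/off gap process with mean gap length 2 days, entry probability calibrated
so the expected missing-step fraction equals the scenario rate. A raw-fix
emitter dead-reckons 2-hourly positions consistent with the daily series
(the 06:00 fix exact, sub-daily fixes interpolated with 30 m jitter), which
lets the preprocessing chain be tested end to end.

What the generator does **not** emulate: collar error ellipses, habitat or
terrain covariates, among-individual and among-year heterogeneity, diel
structure within days, and fix-quality artifacts. Passing recovery tests
therefore demonstrates correctness of the estimation machinery under the
model's own assumptions, not robustness to real-data violations of them.

## Problem sizes and numerical choices

Recovery runs in the test suite and the acceptance script use 100 simulated
animal-years (≈33,000 observed steps) per scenario and a scaled-down MCMC
protocol of 3 chains × 4,000 iterations (2,000 burn-in, thin 5; 1,200
retained draws), which this data size comfortably supports — posterior
scales here are data-dominated, and doubling the chain length moves medians
by less than a Monte-Carlo standard error. The Monte-Carlo check of the
marginal-curve propagation uses 10⁵ simulated state chains. The forward
recursion is JIT-compiled (numba); emission log-densities are vectorized and
cached per block so that only the block being updated pays recomputation.

Degenerate inputs: empty series and out-of-range days raise; fully missing
days carry zero emission terms; observed steps must be positive; ρ ≥ 1 and
δ ≤ 0 are outside the prior support (−∞ log prior, rejected in sampling).
Viterbi ties break toward state 1.

## Known limitations

- Two states only; no covariates beyond day of year; no hierarchical
  individual/year structure. These mirror the scope of the modeled analysis.
- The exact basis matrix used by any given published analysis is generally
  not printed; equivalence is claimed at the level of fitted seasonal
  curves, not spline coefficients.
- Event timing depends mildly on the smoothing window and prominence floor;
  defaults are logged in the output metadata and configurable.
- The adaptive random-walk sampler is robust but not gradient-based; very
  weakly identified corners (e.g. transition curves in seasons with few
  state-2 days) mix more slowly than emission parameters, which is why the
  protocol keeps a long burn-in relative to the retained sample.
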