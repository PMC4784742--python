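# Methods

`isosentinel` estimates, for each specimen captured at a monitored site,
(a) a posterior distribution over candidate geographic source regions and
(b) the latent number of days between arrival and capture, from a single
hydrogen-isotope measurement (δ²H, ‰ vs. VSMOW). The motivating use case
is surveillance of an invading insect at a port of entry: a capture that
still carries the isotopic signature of a distant source region is a new
arrival, while one equilibrated with the local environment has been
present long enough to raise establishment concerns.

## Model structure

Inference is staged ("cut"): three sub-models are fitted in a fixed order
and each downstream stage consumes *stored posterior draws* from the
stages above it, never feeding information back. This modularization
keeps the monitored-site data from distorting the calibration and
turnover estimates, whose experiments are the sole legitimate evidence
for those parameters.

### 1. Isotope turnover (lag–ramp–plateau)

Relocated individuals keep their source δ²H for about two weeks, then
shift linearly, reaching the new environment's value around five weeks:

    μ(t) = δ²H_Init                                  t ≤ 14 d
    μ(t) = δ²H_Init + q(t)·(δ²H_Final − δ²H_Init)    14 ≤ t ≤ 35 d
    μ(t) = δ²H_Final                                 t ≥ 35 d

with q(t) = clamp(a + b·(t − 14), 0, 1). Residual variance is estimated
separately for the pre/ramp/post groups. The onset and completion times
are derived per posterior draw as T₀ = −a/b + 14 and T₁ = (1 − a)/b + 14,
so their credible intervals are percentiles of transformed draws, not
transforms of posterior means.

**Ramp convention.** Writing the ramp on shifted time s = t − 14 makes the
T₀/T₁ definitions above exact. The unshifted form q = clamp(a + b·t, 0, 1)
is retained behind `ramp_convention="literal"` for comparison; it is
internally inconsistent with those definitions (a slope of 0.047/d with
onset near day 13 implies an intercept near 0.03 only under the shifted
form) and is not the default.

**Boundary convention.** Observations at exactly 14 or 35 days are
assigned to the pre and post variance groups respectively; the piecewise
mean is written with overlapping ≤/≥ at those days, so this is a
tie-break, not a modelling statement.

### 2. Voucher calibration and the precipitation measurement model

Specimens of known collection site ("vouchers") calibrate the offset Δ
between organism δ²H and precipitation δ²H:

    δ²H_v ~ Normal(Δ + δ²H_Ppt[l(v), m(v)], σ²_VS)

The collection *month* m(v) is latent with a uniform prior over the 12
months, updated by exact enumeration of its full conditional each sweep.

The true monthly precipitation value is itself latent: the isoscape
calculator supplies monthly *predictions* and a variance for the *annual
mean*. A Berkson-type model places the truth around the prediction,

    δ²H_Ppt[l, m] ~ Normal(pred[l, m], σ²_monthly[l]),

with the annual-mean variance scaled up to a monthly variance via the
variance of a mean of N = 12 correlated values:
σ²_monthly = Var(annual) · N²/(N + 2·Σρ_ij). The 66 pairwise inter-month
correlations are estimated from the monthly predictions across all
non-monitored locations, and the single resulting factor is applied to
every location. In the strongly correlated regime typical of
precipitation isoscapes (mean ρ ≈ 0.96) the factor is ≈ 1.04 — monthly
uncertainty barely exceeds annual uncertainty. If the input supplies a
standard error rather than a variance it must be squared on ingest.

Latent truths are re-drawn every MCMC iteration rather than plugged in,
so isoscape uncertainty propagates into every downstream quantity.

### 3. Monitored-site mixing model

Each captured beetle's δ²H is a two-end-member mixture:

    δ²H_i ~ Normal(μδ_i, σ²_i)
    μδ_i  = p_i·δ²H_PDX,d(i) + (1 − p_i)·δ²H_Src_i,d(i)
    σ²_i  = p_i·σ²_PDX + (1 − p_i)·(σ²_Source·I[Src_i<58] + σ²_Comp·I[Src_i=58])

Monthly end-members are Δ + precipitation truth; date-specific values are
weighted averages over the 90-day window preceding capture (the adult
life-span), with month weights proportional to the days of the window in
each calendar month. The mixing fraction p_i is the turnover ramp
evaluated at the latent time-since-arrival, p_i = clamp(a + b·(Time_i −
14), 0, 1), using (a, b) draws from stage 1.

Latent quantities per beetle: the source region Src_i, a categorical over
57 candidates plus a composite 58th region, and Time_i with a truncated
lognormal prior, Time_i ~ LogNormal(μTime_yr(i), σ²Time_yr(i)) on
(0.5, 60) days, hierarchically pooled within capture year.

**Source prior.** π_j is proportional to annual inbound flights from
region j (scaled to total 0.80), or uniform in the "flat" variant used to
assess what the isotopes alone resolve; the composite region holds fixed
prior mass 0.20 in both.

**Composite end-member.** The composite region exists to absorb δ²H
values that no candidate source can produce. Its end-member is an
unknown month-constant value with a vague Normal(0, 10⁶ ‰²) prior,
estimated jointly. This is the one structural quantity the model
invents; its posterior is only meaningful when such unexplained values
actually occur.

## Priors

Standard deviations: Uniform(0, 100) ‰ (sampled on the log scale with the
uniform prior enforced through the density). Δ: Normal(0, 10⁵ ‰²).
δ²H_Init, δ²H_Final, a, b: Normal(0, 10⁷), with b > 0 by rejection.
μTime: Normal(0, 10⁶) on the log scale.

## Sampler

A blocked Metropolis-within-Gibbs sampler (the clamped ramp is
non-differentiable, the sources and months are discrete, and the cut
forbids joint sampling, which rules out off-the-shelf gradient samplers):

- (δ²H_Init, δ²H_Final) — exact bivariate conjugate Gibbs given the ramp;
- latent months — exact enumeration (Gibbs) over 12 categories;
- precipitation truths, Δ — conjugate normal draws;
- (a, b) — joint random-walk Metropolis, scale adapted during burn-in;
- latent log-times — vectorized random-walk Metropolis with reflection at
  the truncation bounds, step size tuned toward 20–40% acceptance during
  burn-in only;
- (μTime, σTime) per year — independence proposal centred on the
  empirical mean of the year's log-times (with the truncation constant in
  the MH correction) and a log-scale move for σ;
- residual SDs and the composite end-member — Metropolis on the marginal
  likelihood; the composite move mixes local steps with occasional large
  jumps because that parameter can be multimodal when the data are
  explainable without it.

**Marginalized sources.** The discrete source is summed out of the
likelihood (an exact 58-term sum) for every continuous update, avoiding
sticky categorical moves; per-beetle posterior source probabilities are
recovered as Monte-Carlo averages of the normalized mixture weights,
which is exactly equivalent in expectation.

**Cut propagation.** Each mixing-stage iteration consumes one stored
(a, b, Δ) draw, cycling through the stored draws in a per-chain random
permutation — multiple imputation of the upstream uncertainty. A
permutation rather than the raw draw order avoids aliasing the cycle with
upstream autocorrelation. (a, b) draws stay paired; Δ comes from an
independent stage.

**Defaults.** Three chains, 20,000 iterations, burn-in 5,000 (chains
reach R̂ < 1.1 well within the burn-in on the calibration and turnover
stages; the weakly identified mixing-stage hyperparameters converge more
slowly), posterior summaries as means with central 95% intervals (2.5th/
97.5th percentiles of pooled post-burn-in draws), convergence monitored
with the Brooks–Gelman–Rubin potential scale reduction factor.

## Synthetic data generator

The generator produces every input with known ground truth, sized by
default like the motivating study: 57 candidate sources plus the
composite, 15 voucher sites, 100 vouchers, 101 monitored-site beetles,
and 62 turnover beetles over six weekly harvests. Its structural choices:

- **Isoscape**: monthly prediction = lat/lon trend (−3 ‰/° latitude,
  +1.2 ‰/° longitude, so values are highest in the southeast and lowest
  at the far-northwest monitored site) + a shared summer-peaking sinusoid
  (amplitude 12 ‰) + site-month noise scaled so the realized mean
  inter-month correlation matches the 0.96 target. Candidate sources sit
  in the east; the monitored site's end-member lies below every source,
  as in the real continental gradient.
- **Calibration truth**: Δ = −48 ‰, σ_VS = 6 ‰, months uniform.
- **Turnover truth**: a = 0.03, b = 0.047/d, δ²H from −60 to −110 ‰,
  group SDs (4, 6, 4) ‰.
- **Cohort truth**: year-level mean times falling from ~35–44 days
  (2007–2010) through ~20 (2011) to ~5–7 days (2012–2014), lognormal
  σ = 0.5; traffic-weighted sources with 20% composite mass; composite
  end-member −30 ‰, above every source value.
- **Surveillance**: beetles-per-aircraft declining 15%/yr from 1991 with
  mild lognormal noise.

What the generator does *not* emulate: spatially continuous isoscapes
(sites are independent draws around the trend), beetle phenology by
source climate, multi-leg transport, tissue-specific turnover, and
measurement-batch effects. Passing recovery tests therefore demonstrates
that the inference machinery is correct and well calibrated under the
model's own assumptions, not that the model is adequate for any
particular real dataset.

## Numerical choices

- Marginal likelihoods use the max-shift log-sum-exp; oracle tests require
  agreement with direct enumeration to 1e-12 relative tolerance.
- The truncated lognormal's normalizer and mean use stable log-space
  Gaussian-mass differences, so diffuse hyperparameter draws cannot
  overflow; the per-year population-mean summary uses the *truncated*
  mean, which stays inside (0.5, 60) by construction.
- CSV round-trips are bit-exact: floats are written with `%.17g` and read
  with the round-trip parser.
- Window weights are computed by exact calendar enumeration of the 90
  days ending on the capture date (Gregorian, leap years respected); a
  90-day window spans at most four calendar months.
- Zero beetles-per-aircraft years are excluded from the log-linear
  decline fit; a sensitivity variant substituting half the smallest
  positive value is reported alongside.
- "Inverse of the credible interval" weighting in the latitude regression
  is read as 1/(upper − lower), the only dimensionally sensible reading.
- The annual precipitation mean used in the descriptive voucher
  regression is the unweighted mean of the 12 monthly predictions.

## Problem sizes used in the shipped checks

Parameter-recovery checks run 50 replicates of the turnover experiment
(62 beetles) and of the calibration (100 vouchers) at reduced chain
lengths (3×4,000 and 3×2,500, burn-in 1,500/800), which is ample for
these small conjugate-dominated posteriors; the monitored-cohort recovery
runs the full default scenario at the default 3×20,000. The acceptance
script runs the complete pipeline, including the flat-prior variant, at
the default lengths.

## Known limitations

- With ~100 specimens, the residual SDs of the mixing stage (σ_Source,
  σ_Composite) are weakly identified; their posteriors are broad and the
  composite end-member can be multimodal when no specimen needs it.
- Times in the clamp regions (below T₀ or above T₁) are informed only
  through the year-level prior; resolution finer than the ~14-day lag is
  not attainable, and per-year mean-time intervals are accordingly wide.
- Geographic resolution among isotopically similar sources rests almost
  entirely on the prior; the flat-prior variant shows what the isotopes
  alone support (a broad north–south gradient, not a specific region).
- The sampler is single-threaded; the default three-chain mixing-stage
  fit takes a few minutes at study scale.
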