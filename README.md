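# isosentinel

Hierarchical Bayesian assignment of **geographic origin** and
**time-since-arrival** from hydrogen stable isotopes.

When an invasive insect is trapped at a monitored port of entry, the key
management question is whether it is a fresh arrival from an established
population elsewhere or a member of a nascent local population. A single
δ²H measurement (‰ vs. VSMOW) carries both signals: tissue δ²H tracks the
precipitation δ²H of the region where the tissue grew, and after
relocation it drifts linearly toward the new environment's value over a
known time course. `isosentinel` turns that measurement into posterior
distributions over 57+1 candidate source regions and over the days
elapsed between arrival and capture.

The package is aimed at quantitative ecologists and invasion-surveillance
analysts; it ships a synthetic-data generator with known ground truth, so
every stage is testable without any external download.

## The model

Three sub-models, fitted in a staged ("cut") pipeline with no downstream
feedback:

1. **Turnover** — after relocation, expected δ²H follows a lag–ramp–
   plateau: the source value δ²H_Init for t ≤ 14 d, the equilibrated
   value δ²H_Final for t ≥ 35 d, and a linear blend with fraction
   q(t) = clamp(a + b·(t − 14), 0, 1) between. Derived onset and
   completion times: T₀ = −a/b + 14, T₁ = (1 − a)/b + 14.
2. **Calibration** — vouchers of known site and latent collection month
   estimate the organism-vs-precipitation offset:
   δ²H_v ~ N(Δ + δ²H_Ppt[l(v), m(v)], σ²_VS), with a Berkson measurement
   model for the true monthly precipitation value around the isoscape
   prediction (annual variance scaled by N²/(N + 2Σρ) ≈ 1.04).
3. **Mixing** — each capture i is a two-end-member mixture
   δ²H_i ~ N(p_i·δ²H_PDX + (1 − p_i)·δ²H_Src_i, σ²_i), with p_i the
   turnover ramp at the latent time-since-arrival, Time_i truncated-
   lognormal on (0.5, 60) days pooled by capture year, a latent discrete
   source with a flight-traffic (or flat) prior, and a composite region
   of prior mass 0.20 absorbing values no candidate source can produce.
   End-members average the monthly values over the 90-day window before
   capture.

Inference is a custom blocked Metropolis-within-Gibbs sampler (three
chains, 20,000 iterations by default, Brooks–Gelman–Rubin diagnostics);
the discrete source is marginalized exactly inside the likelihood. See
`docs/methods.md` for the full account.

## Worked example

```python
import numpy as np
from isosentinel import (ScenarioSpec, simulate_all, fit_turnover_model,
                         fit_voucher_model, McmcConfig)

ds = simulate_all(ScenarioSpec(seed=1))   # full synthetic study

post = fit_turnover_model(ds.inputs.turnover,
                          McmcConfig(n_chains=3, n_iter=4000, n_burn=1500, seed=0))
for name in ("b", "t0", "t1"):
    draws = getattr(post, f"{name}_draws")
    lo, hi = np.percentile(draws, [2.5, 97.5])
    print(f"{name}: {draws.mean():.3f} [{lo:.3f}, {hi:.3f}]")

cal = fit_voucher_model(ds.inputs.vouchers, ds.inputs.locations,
                        McmcConfig(n_chains=3, n_iter=2500, n_burn=800, seed=0))
lo, hi = np.percentile(cal.delta_draws, [2.5, 97.5])
print(f"delta: {cal.delta_draws.mean():.1f} [{lo:.1f}, {hi:.1f}]")
```

prints

```
b: 0.062 [0.043, 0.081]
t0: 14.710 [11.108, 17.427]
t1: 31.451 [28.857, 35.146]
delta: -47.2 [-49.4, -44.9]
```

The turnover slope `b` is the per-day fraction of the isotopic shift
(this realization drew 0.062/d against a generating value of 0.047/d,
inside the interval); `t0`/`t1` bracket the days before the signal starts
moving and until full equilibration; `delta` recovers the −48 ‰
beetle-vs-precipitation offset the data were generated with. The full
pipeline (`isosentinel.run_pipeline`) adds the mixing stage and returns
per-specimen time posteriors and source probabilities.

A CLI mirrors the stages:

```sh
isosentinel simulate --seed 1 --out data/
isosentinel fit-pdx data/ --out results/ --prior traffic
isosentinel report data/ --out results/report.txt
```

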