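"""A small blocked Metropolis-within-Gibbs engine with convergence diagnostics.

The staged (cut) inference used here precludes off-the-shelf gradient
samplers: the mixing fraction is a clamped — hence non-differentiable —
function of latent time, latent months and sources are discrete, and
upstream posteriors must feed downstream stages without feedback. Each
stage therefore defines a *model* object with three methods:

- ``init_state(rng, dispersion)``: a dict of state variables, overdispersed
  starting values scaled by ``dispersion``;
- ``step(state, rng, iteration, adapting)``: one full sweep of block
  updates (conjugate Gibbs where available, random-walk Metropolis
  elsewhere; proposal scales may adapt only while ``adapting`` is True);
- ``tracked(state)``: the scalar/vector quantities to record per iteration.

An optional ``accumulate(state)`` returns arrays to be averaged over
post-burn-in iterations (used for per-specimen source probabilities, which
are too large to store per draw).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Protocol

import numpy as np
import pandas as pd

from .datatypes import ValidationError

__all__ = ["McmcConfig", "ModelPosterior", "gelman_rubin", "run_mcmc",
           "sigma_logscale_update"]


@dataclass
class McmcConfig:
    """Chain count, length, burn-in, and per-chain seeding."""

    n_chains: int = 3
    n_iter: int = 20000
    n_burn: int = 5000
    seed: int = 0
    seeds: tuple[int, ...] | None = None
    init_dispersion: float = 1.0

    def __post_init__(self) -> None:
        if self.n_chains < 2:
            raise ValidationError("n_chains must be >= 2 for convergence diagnostics")
        if self.n_iter <= self.n_burn:
            raise ValidationError("n_iter must exceed n_burn")
        if self.seeds is not None and len(self.seeds) != self.n_chains:
            raise ValidationError("need one seed per chain")

    def chain_rngs(self) -> list[np.random.Generator]:
        if self.seeds is not None:
            return [np.random.default_rng(s) for s in self.seeds]
        ss = np.random.SeedSequence(self.seed)
        return [np.random.default_rng(child) for child in ss.spawn(self.n_chains)]


class Model(Protocol):  # pragma: no cover - structural type only
    def init_state(self, rng: np.random.Generator, dispersion: float) -> dict: ...
    def step(self, state: dict, rng: np.random.Generator,
             iteration: int, adapting: bool) -> None: ...
    def tracked(self, state: dict) -> dict[str, Any]: ...


def gelman_rubin(draws: np.ndarray) -> float:
    """Potential scale reduction factor R̂ for one quantity.

    ``draws`` has shape (n_chains, n_iterations). Uses the between/within
    variance form: R̂ = sqrt(((n-1)/n · W + B/n) / W). Returns 1.0 by
    convention when both variance components vanish.
    """
    x = np.asarray(draws, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 10:
        raise ValidationError("need >= 2 chains and >= 10 iterations for R-hat")
    n = x.shape[1]
    w = x.var(axis=1, ddof=1).mean()
    b_over_n = x.mean(axis=1).var(ddof=1)
    if w == 0:
        return 1.0 if b_over_n == 0 else np.inf
    var_plus = (n - 1) / n * w + b_over_n
    return float(np.sqrt(var_plus / w))


@dataclass
class ModelPosterior:
    """MCMC draws plus posterior summaries.

    ``draws[name]`` has shape (n_chains, n_kept) for scalars or
    (n_chains, n_kept, k) for length-k vector quantities. Summaries are
    posterior means with central 95% credible intervals (2.5th and 97.5th
    percentiles of the pooled post-burn-in draws).
    """

    draws: dict[str, np.ndarray]
    summaries: pd.DataFrame
    rhat: dict[str, float]
    accumulators: dict[str, np.ndarray] = field(default_factory=dict)
    config: McmcConfig | None = None

    def pooled(self, name: str) -> np.ndarray:
        d = self.draws[name]
        return d.reshape(-1, *d.shape[2:])

    def mean(self, name: str) -> float | np.ndarray:
        out = self.pooled(name).mean(axis=0)
        return float(out) if np.ndim(out) == 0 else out

    def ci(self, name: str) -> np.ndarray:
        return np.percentile(self.pooled(name), [2.5, 97.5], axis=0)

    @property
    def max_rhat(self) -> float:
        return max(self.rhat.values())

    @property
    def converged(self) -> bool:
        return self.max_rhat < 1.1


def summarize(draws: dict[str, np.ndarray]) -> tuple[pd.DataFrame, dict[str, float]]:
    rows = []
    rhats: dict[str, float] = {}
    for name, arr in draws.items():
        pooled = arr.reshape(-1, *arr.shape[2:])
        if arr.ndim == 2:
            r = gelman_rubin(arr)
            rhats[name] = r
            lo, hi = np.percentile(pooled, [2.5, 97.5])
            rows.append({"param": name, "mean": pooled.mean(),
                         "ci_lower": lo, "ci_upper": hi, "rhat": r})
        else:
            k = arr.shape[2]
            r_elem = np.array([gelman_rubin(arr[:, :, i]) for i in range(k)])
            rhats[name] = float(r_elem.max())
            lo, hi = np.percentile(pooled, [2.5, 97.5], axis=0)
            mean = pooled.mean(axis=0)
            rows.extend(
                {"param": f"{name}[{i}]", "mean": mean[i],
                 "ci_lower": lo[i], "ci_upper": hi[i], "rhat": r_elem[i]}
                for i in range(k)
            )
    return pd.DataFrame(rows), rhats


def run_mcmc(model: Model, config: McmcConfig,
             max_init_retries: int = 20) -> ModelPosterior:
    """Run parallel chains of a block-update model and summarize.

    Starting states with a non-finite log posterior (when the model exposes
    ``log_posterior``) are re-drawn up to ``max_init_retries`` times.
    Identical config (seeds included) yields a bit-identical draw sequence.
    """
    n_kept = config.n_iter - config.n_burn
    draws: dict[str, np.ndarray] = {}
    acc_sums: dict[str, np.ndarray] = {}
    has_accum = hasattr(model, "accumulate")

    for c, rng in enumerate(config.chain_rngs()):
        state = model.init_state(rng, config.init_dispersion)
        if hasattr(model, "log_posterior"):
            for _ in range(max_init_retries):
                if np.isfinite(model.log_posterior(state)):
                    break
                state = model.init_state(rng, config.init_dispersion)
            else:
                raise RuntimeError("could not find a finite-density starting state")
        for it in range(config.n_iter):
            model.step(state, rng, it, adapting=it < config.n_burn)
            if it < config.n_burn:
                continue
            kept = it - config.n_burn
            for name, value in model.tracked(state).items():
                value = np.asarray(value, dtype=float)
                if name not in draws:
                    shape = (config.n_chains, n_kept) + value.shape
                    draws[name] = np.empty(shape)
                draws[name][c, kept] = value
            if has_accum:
                for name, value in model.accumulate(state).items():
                    if name not in acc_sums:
                        acc_sums[name] = np.zeros_like(np.asarray(value, dtype=float))
                    acc_sums[name] += value

    summaries, rhats = summarize(draws)
    total = config.n_chains * n_kept
    accumulators = {k: v / total for k, v in acc_sums.items()}
    return ModelPosterior(draws=draws, summaries=summaries, rhat=rhats,
                          accumulators=accumulators, config=config)


def sigma_logscale_update(sigma: float, loglik, rng: np.random.Generator,
                          step: float = 0.3, upper: float = 100.0) -> float:
    """Random-walk Metropolis update of a standard deviation on the log scale.

    The prior is Uniform(0, ``upper``) on σ itself; the log-scale move
    carries the Jacobian term log σ. ``loglik(sigma)`` returns the
    log-likelihood holding everything else fixed.
    """
    prop = sigma * np.exp(step * rng.standard_normal())
    if prop >= upper:
        return sigma
    log_ratio = loglik(prop) - loglik(sigma) + np.log(prop) - np.log(sigma)
    if np.log(rng.uniform()) < log_ratio:
        return prop
    return sigma
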