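"""Calibration of the beetle-vs-precipitation δ²H offset from vouchers.

Voucher beetles have a known collection site but an unknown collection
month, so the month enters as a latent variable with a uniform prior over
the 12 months. Each voucher's δ²H is modelled as

    δ²H_v ~ Normal(Δ + δ²H_Ppt[l(v), m(v)], σ²_VS)

where the true monthly precipitation value is itself latent with a Berkson
prior around the calculator prediction. Latent months are updated by exact
enumeration of the 12 full conditionals (Gibbs), Δ and the precipitation
truths by conjugate normal draws, and σ_VS on the log scale under its
Uniform(0, 100) prior.

The calibration is fitted as its own stage and its draws stored; the
downstream mixing model consumes the stored draws (the "cut"), so the
monitored-site data can never feed back into Δ.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .datatypes import LocationRecord, SpecimenRecord, ValidationError
from .mcmc import McmcConfig, ModelPosterior, run_mcmc, sigma_logscale_update
from .precip import monthly_variance_factor, pairwise_month_correlations

__all__ = ["CalibrationPosterior", "voucher_loglik", "end_member",
           "VoucherModel", "fit_voucher_model"]

_DELTA_PRIOR_VAR = 1e5

_LOG_SQRT_2PI = 0.5 * np.log(2 * np.pi)


def voucher_loglik(specimen: SpecimenRecord, month: int, delta: float,
                   sigma_vs: float, precip_truth: float) -> float:
    """Normal log-density of a voucher's δ²H at Δ + truth for its site-month."""
    if not 1 <= month <= 12:
        raise ValidationError(f"month must be in 1..12, got {month}")
    if sigma_vs <= 0:
        raise ValidationError("sigma_vs must be > 0")
    mu = delta + precip_truth
    z = (specimen.d2h - mu) / sigma_vs
    return float(-0.5 * z * z - np.log(sigma_vs) - _LOG_SQRT_2PI)


def end_member(delta, precip_truth):
    """Beetle end-member δ²H for a location-month: Δ + precipitation truth."""
    return np.asarray(delta, dtype=float) + np.asarray(precip_truth, dtype=float)


@dataclass
class CalibrationPosterior:
    """Posterior draws of the offset and per-voucher month probabilities."""

    delta_draws: np.ndarray
    sigma_vs_draws: np.ndarray
    month_probs: np.ndarray  # (n_vouchers, 12), rows sum to 1
    posterior: ModelPosterior
    voucher_ids: list[str] | None = None


class VoucherModel:
    """Gibbs/Metropolis blocks for the voucher-precipitation calibration."""

    def __init__(self, d2h: np.ndarray, loc_idx: np.ndarray,
                 preds: np.ndarray, monthly_var: np.ndarray):
        self.d2h = np.asarray(d2h, dtype=float)        # (n,)
        self.loc_idx = np.asarray(loc_idx, dtype=int)  # (n,) into locations
        self.preds = np.asarray(preds, dtype=float)    # (L, 12)
        self.monthly_var = np.asarray(monthly_var, dtype=float)  # (L,)
        self.n = self.d2h.size
        self.L = self.preds.shape[0]

    def init_state(self, rng: np.random.Generator, dispersion: float) -> dict:
        # start Δ near the gap between voucher values and annual-mean predictions
        rough = float(np.mean(self.d2h - self.preds[self.loc_idx].mean(axis=1)))
        return {
            "delta": rough + dispersion * rng.normal(0, 10),
            "sigma_vs": float(np.clip(
                np.exp(np.log(10.0) + dispersion * rng.normal(0, 0.5)), 0.5, 99.0)),
            "months": rng.integers(0, 12, self.n),
            "truth": self.preds + rng.normal(
                0, np.sqrt(self.monthly_var)[:, None], self.preds.shape),
            "_month_probs": np.full((self.n, 12), 1.0 / 12),
        }

    def log_posterior(self, state: dict) -> float:
        mu = state["delta"] + state["truth"][self.loc_idx, state["months"]]
        sig = state["sigma_vs"]
        if not 0 < sig < 100:
            return -np.inf
        lp = -0.5 * np.sum(((self.d2h - mu) / sig) ** 2) - self.n * np.log(sig)
        lp += -0.5 * state["delta"] ** 2 / _DELTA_PRIOR_VAR
        lp += -0.5 * np.sum((state["truth"] - self.preds) ** 2
                            / self.monthly_var[:, None])
        return float(lp)

    def step(self, state: dict, rng: np.random.Generator,
             iteration: int, adapting: bool) -> None:
        delta, sigma = state["delta"], state["sigma_vs"]
        truth, months = state["truth"], state["months"]

        # latent months: exact enumeration of the 12 full conditionals
        mu_all = delta + truth[self.loc_idx]              # (n, 12)
        logp = -0.5 * ((self.d2h[:, None] - mu_all) / sigma) ** 2
        logp -= logp.max(axis=1, keepdims=True)
        probs = np.exp(logp)
        probs /= probs.sum(axis=1, keepdims=True)
        u = rng.uniform(size=self.n)
        months[:] = (probs.cumsum(axis=1) < u[:, None]).sum(axis=1)
        state["_month_probs"] = probs

        # precipitation truths: conjugate normal per (location, month)
        resid = self.d2h - delta
        n_lm = np.zeros((self.L, 12))
        s_lm = np.zeros((self.L, 12))
        np.add.at(n_lm, (self.loc_idx, months), 1.0)
        np.add.at(s_lm, (self.loc_idx, months), resid)
        prec = 1.0 / self.monthly_var[:, None] + n_lm / sigma ** 2
        mean = (self.preds / self.monthly_var[:, None] + s_lm / sigma ** 2) / prec
        truth[:] = mean + rng.standard_normal(truth.shape) / np.sqrt(prec)

        # offset Δ: conjugate normal
        r = self.d2h - truth[self.loc_idx, months]
        prec_d = self.n / sigma ** 2 + 1.0 / _DELTA_PRIOR_VAR
        mean_d = (r.sum() / sigma ** 2) / prec_d
        state["delta"] = float(rng.normal(mean_d, 1.0 / np.sqrt(prec_d)))

        # residual standard deviation
        mu = state["delta"] + truth[self.loc_idx, months]
        resid2 = self.d2h - mu

        def loglik(s: float) -> float:
            return float(-0.5 * np.sum((resid2 / s) ** 2) - self.n * np.log(s))

        state["sigma_vs"] = sigma_logscale_update(state["sigma_vs"], loglik, rng)

    def tracked(self, state: dict) -> dict:
        return {"delta": state["delta"], "sigma_vs": state["sigma_vs"]}

    def accumulate(self, state: dict) -> dict:
        # Rao-Blackwellized month probabilities (full-conditional weights)
        return {"month_probs": state["_month_probs"]}


def fit_voucher_model(vouchers: Sequence[SpecimenRecord],
                      locations: Sequence[LocationRecord],
                      mcmc_config: McmcConfig | None = None,
                      variance_factor: float | None = None) -> CalibrationPosterior:
    """Fit the offset Δ, residual σ_VS and latent months to voucher data.

    ``locations`` must contain the voucher sites; the annual-to-monthly
    variance scaling factor is computed from all non-monitored locations
    unless supplied.
    """
    mcmc_config = mcmc_config or McmcConfig()
    vouchers = [v for v in vouchers if v.cohort == "voucher"]
    if not vouchers:
        raise ValidationError("no voucher specimens supplied")
    loc_by_id = {loc.location_id: loc for loc in locations}
    missing = {v.location_id for v in vouchers} - set(loc_by_id)
    if missing:
        raise ValidationError(f"voucher location(s) not in locations: {sorted(missing)}")

    site_ids = sorted({v.location_id for v in vouchers})
    if len(site_ids) < 2:
        warnings.warn(
            "vouchers come from a single site: the offset and the site truth "
            "are confounded; expect a wide, poorly identified posterior",
            stacklevel=2)

    if variance_factor is None:
        mat = np.array([loc.precip_monthly_pred for loc in locations
                        if loc.role != "pdx"])
        rho, _ = pairwise_month_correlations(mat)
        variance_factor = monthly_variance_factor(12, rho)

    site_index = {s: i for i, s in enumerate(site_ids)}
    preds = np.array([loc_by_id[s].precip_monthly_pred for s in site_ids])
    mvar = np.array([variance_factor * loc_by_id[s].precip_annual_var
                     for s in site_ids])
    d2h = np.array([v.d2h for v in vouchers])
    loc_idx = np.array([site_index[v.location_id] for v in vouchers])

    model = VoucherModel(d2h, loc_idx, preds, mvar)
    post = run_mcmc(model, mcmc_config)
    if not post.converged:
        warnings.warn(
            f"voucher fit: max R-hat {post.max_rhat:.3f} >= 1.1; "
            f"results returned but treat with caution", stacklevel=2)
    month_probs = post.accumulators["month_probs"]
    return CalibrationPosterior(
        delta_draws=post.pooled("delta"),
        sigma_vs_draws=post.pooled("sigma_vs"),
        month_probs=month_probs,
        posterior=post,
        voucher_ids=[v.specimen_id for v in vouchers])
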