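"""Per-specimen mixture of source and local end-members with latent
source region and latent time-since-arrival.

Each beetle caught at the monitored site is modelled as

    δ²H_i ~ Normal(μδ_i, σ²_i)
    μδ_i  = p_i · δ²H_PDX,d(i) + (1 − p_i) · δ²H_Src_i,d(i)

where p_i is the fraction of the local ("PDX") end-member, a clamped
linear function of the latent time-since-arrival (shared with the
turnover ramp), and Src_i is a latent discrete source among 57 candidate
regions plus a composite 58th region for values unexplained by any
candidate. The residual variance mixes the same way:

    σ²_i = p_i·σ²_PDX + (1 − p_i)·(σ²_Source·I[Src<58] + σ²_Composite·I[Src=58])

Date-specific end-members are 90-day window averages of monthly
end-members (Δ + true monthly precipitation δ²H), and latent times carry a
truncated lognormal prior, LogNormal(μTime_yr, σ²Time_yr) on (0.5, 60) days,
with year-specific hyperparameters.

The discrete source is marginalized inside the likelihood (an exact
58-term sum), which removes sticky categorical moves from the sampler;
per-beetle posterior source probabilities are recovered as Monte-Carlo
averages of the normalized mixture weights. Upstream uncertainty in
(a, b) and Δ enters by cycling through stored posterior draws — a
multiple-imputation realization of the cut, with no downstream feedback.
"""

from __future__ import annotations

import datetime as _dt
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import log_ndtr, ndtr

from .datatypes import (LocationRecord, SpecimenRecord, TrafficRecord,
                        ValidationError)
from .mcmc import McmcConfig, ModelPosterior, run_mcmc, sigma_logscale_update
from .precip import monthly_variance_factor, pairwise_month_correlations
from .turnover import TurnoverPosterior, q_fraction
from .voucher import CalibrationPosterior

__all__ = [
    "SourcePrior", "BeetleLatentState", "MixingHyperparams",
    "window_weights", "weighted_end_member", "mixture_mean",
    "mixture_variance", "p_from_time", "time_prior_logpdf",
    "build_source_prior", "beetle_loglik_marginal",
    "PdxModel", "PdxPosterior", "fit_pdx_model",
]

_LOG_2PI = np.log(2 * np.pi)
_MU_TIME_PRIOR_VAR = 1e6
_MU_COMP_PRIOR_VAR = 1e6


@dataclass
class SourcePrior:
    """Prior source-region probabilities π, composite region last.

    In ``traffic`` mode the 57 candidate-region probabilities are
    proportional to annual inbound flights, scaled to total 1 − the
    composite mass; in ``flat`` mode they are equal. The composite region
    keeps its fixed prior mass in both modes.
    """

    probs: np.ndarray
    mode: str
    region_ids: list[str]
    composite_mass: float = 0.20

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.size != len(self.region_ids) + 1:
            raise ValidationError("probs must have one entry per region plus composite")
        if not np.isclose(self.probs.sum(), 1.0):
            raise ValidationError("source prior probabilities must sum to 1")
        if not np.isclose(self.probs[-1], self.composite_mass):
            raise ValidationError(
                f"composite prior mass must be {self.composite_mass}")

    @property
    def n_regions(self) -> int:
        return self.probs.size

    @property
    def log_probs(self) -> np.ndarray:
        with np.errstate(divide="ignore"):
            return np.log(self.probs)


@dataclass
class BeetleLatentState:
    """Latent quantities for one monitored-site beetle."""

    time_since_arrival: float
    source: int          # 1-based region index; n_regions = composite
    p_mix: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_mix <= 1.0:
            raise ValidationError("p_mix must lie in [0, 1]")


@dataclass
class MixingHyperparams:
    """Residual SDs of the mixture and year-level time hyperparameters."""

    sigma_pdx: float
    sigma_source: float
    sigma_composite: float
    mu_time_by_year: dict[int, float] = field(default_factory=dict)
    sigma_time_by_year: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("sigma_pdx", "sigma_source", "sigma_composite"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")


def window_weights(collection_date: _dt.date,
                   window_days: int = 90) -> tuple[np.ndarray, np.ndarray]:
    """Month weights for the trailing window ending on the collection date.

    The window is the collection day and the preceding ``window_days − 1``
    days. Returns (weights, months): ``weights[j]`` is the fraction of
    window days falling in calendar month j steps before the collection
    month (j = 0 is the collection month itself) and sums to exactly 1;
    ``months[j]`` is that month's calendar number (1..12). A 90-day window
    touches at most 4 calendar months.
    """
    weights = np.zeros(4)
    for k in range(window_days):
        d = collection_date - _dt.timedelta(days=k)
        j = ((collection_date.year - d.year) * 12
             + collection_date.month - d.month)
        if j >= 4:
            raise ValidationError(
                f"window of {window_days} days spans more than 4 months")
        weights[j] += 1.0
    weights /= window_days
    months = np.array([(collection_date.month - 1 - j) % 12 + 1
                       for j in range(4)])
    return weights, months


def weighted_end_member(monthly_end_members, weights) -> float:
    """Date-specific end-member: window-weighted mean of 4 monthly values."""
    v = np.asarray(monthly_end_members, dtype=float)
    w = np.asarray(weights, dtype=float)
    return float(v @ w)


def mixture_mean(p, em_pdx, em_src):
    """Linear blend p·local + (1 − p)·source."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValidationError("p must lie in [0, 1]")
    return p * np.asarray(em_pdx, dtype=float) + (1 - p) * np.asarray(em_src, dtype=float)


def mixture_variance(p: float, source_index: int, hyper: MixingHyperparams,
                     n_regions: int = 58) -> float:
    """Residual variance for a beetle with mixing fraction p and given source.

    ``source_index`` is 1-based; index ``n_regions`` is the composite.
    """
    if not 0 <= p <= 1:
        raise ValidationError("p must lie in [0, 1]")
    if not 1 <= source_index <= n_regions:
        raise ValidationError(f"source index must be in 1..{n_regions}")
    away = (hyper.sigma_composite if source_index == n_regions
            else hyper.sigma_source) ** 2
    return p * hyper.sigma_pdx ** 2 + (1 - p) * away


def p_from_time(a, b, time, convention: str = "shifted"):
    """Local end-member fraction from time-since-arrival (shared ramp)."""
    return q_fraction(a, b, time, convention)


def time_prior_logpdf(time, mu_time: float, sigma_time: float,
                      bounds: tuple[float, float] = (0.5, 60.0)):
    """Truncated-lognormal log-density for time-since-arrival (days).

    Renormalized over ``bounds``; −inf outside the bounds.
    """
    if sigma_time <= 0:
        raise ValidationError("sigma_time must be > 0")
    t = np.asarray(time, dtype=float)
    lo, hi = bounds
    z = (np.log(np.where(t > 0, t, 1.0)) - mu_time) / sigma_time
    log_norm = np.log(ndtr((np.log(hi) - mu_time) / sigma_time)
                      - ndtr((np.log(lo) - mu_time) / sigma_time))
    with np.errstate(divide="ignore"):
        out = (-np.log(t * sigma_time) - 0.5 * _LOG_2PI - 0.5 * z * z - log_norm)
    out = np.where((t <= lo) | (t >= hi), -np.inf, out)
    return out if out.ndim else float(out)


def _log_gauss_mass(a, b):
    """log(Φ(b) − Φ(a)) computed stably in either tail."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    out = np.empty(np.broadcast(a, b).shape)
    a, b = np.broadcast_arrays(a, b)
    left = b <= 0
    right = a >= 0
    mid = ~(left | right)
    # left tail: work with Φ directly; right tail: mirror to the left
    la, lb = a[left], b[left]
    out[left] = log_ndtr(lb) + np.log1p(-np.exp(log_ndtr(la) - log_ndtr(lb)))
    ra, rb = -b[right], -a[right]
    out[right] = log_ndtr(rb) + np.log1p(-np.exp(log_ndtr(ra) - log_ndtr(rb)))
    out[mid] = np.log(ndtr(b[mid]) - ndtr(a[mid]))
    return out


def truncated_lognormal_mean(mu, sigma, bounds: tuple[float, float] = (0.5, 60.0)):
    """Mean of LogNormal(μ, σ²) truncated to ``bounds`` (always inside them).

    E[T | lo < T < hi] = exp(μ + σ²/2) · (Φ(z_hi − σ) − Φ(z_lo − σ))
                                        / (Φ(z_hi) − Φ(z_lo)).
    """
    mu = np.asarray(mu, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    lo, hi = bounds
    z_lo = (np.log(lo) - mu) / sigma
    z_hi = (np.log(hi) - mu) / sigma
    log_mean = (mu + 0.5 * sigma ** 2
                + _log_gauss_mass(z_lo - sigma, z_hi - sigma)
                - _log_gauss_mass(z_lo, z_hi))
    return np.exp(log_mean)


def build_source_prior(traffic: Sequence[TrafficRecord], mode: str,
                       composite_mass: float = 0.20) -> SourcePrior:
    """Source prior from flight counts ('traffic') or uniform ('flat')."""
    if mode not in ("traffic", "flat"):
        raise ValidationError(f"prior mode must be 'traffic' or 'flat', got {mode!r}")
    if not traffic:
        raise ValidationError("no traffic records supplied")
    region_ids = [t.source_region_id for t in traffic]
    n = len(region_ids)
    if mode == "traffic":
        flights = np.array([t.flights_per_year for t in traffic], dtype=float)
        if flights.sum() <= 0:
            raise ValidationError("traffic mode requires at least one region "
                                  "with flights > 0")
        probs = flights / flights.sum() * (1 - composite_mass)
    else:
        probs = np.full(n, (1 - composite_mass) / n)
    return SourcePrior(probs=np.append(probs, composite_mass), mode=mode,
                       region_ids=region_ids, composite_mass=composite_mass)


def beetle_loglik_marginal(d2h: float, time: float, hyper: MixingHyperparams,
                           prior: SourcePrior, em_pdx: float,
                           em_sources: np.ndarray, a: float, b: float,
                           convention: str = "shifted"
                           ) -> tuple[float, np.ndarray]:
    """Source-marginal log-likelihood of one beetle's δ²H.

    ``em_sources`` holds the date-specific end-member for every region
    (composite last). Returns (log Σ_j π_j·N(δ²H | μ_j, σ²_j), posterior
    source weights normalized to 1).
    """
    em_sources = np.asarray(em_sources, dtype=float)
    if em_sources.size != prior.n_regions:
        raise ValidationError("need one source end-member per region")
    p = float(p_from_time(a, b, time, convention))
    mu = mixture_mean(p, em_pdx, em_sources)
    var = np.full(em_sources.size,
                  p * hyper.sigma_pdx ** 2 + (1 - p) * hyper.sigma_source ** 2)
    var[-1] = p * hyper.sigma_pdx ** 2 + (1 - p) * hyper.sigma_composite ** 2
    log_terms = (prior.log_probs - 0.5 * (_LOG_2PI + np.log(var))
                 - 0.5 * (d2h - mu) ** 2 / var)
    m = log_terms.max()
    lse = m + np.log(np.exp(log_terms - m).sum())
    weights = np.exp(log_terms - lse)
    return float(lse), weights


# --------------------------------------------------------------- sampler

class PdxModel:
    """Blocked sampler for the monitored-site mixing model.

    Latent log-times move by vectorized random-walk Metropolis with
    reflection at the truncation bounds (step size tuned during burn-in
    toward 20–40% acceptance); year-level (μTime, σTime), the three
    residual SDs, and the composite end-member move by Metropolis; the
    latent precipitation truths are redrawn from their Berkson
    distribution every iteration; and each iteration consumes one stored
    upstream (a, b, Δ) draw in a per-chain random permutation.
    """

    def __init__(self, d2h: np.ndarray, weight_mat: np.ndarray,
                 month_mat: np.ndarray, year_idx: np.ndarray,
                 pdx_pred: np.ndarray, pdx_mvar: float,
                 src_preds: np.ndarray, src_mvar: np.ndarray,
                 prior: SourcePrior, cut_draws: np.ndarray,
                 time_bounds: tuple[float, float] = (0.5, 60.0),
                 convention: str = "shifted"):
        self.d2h = np.asarray(d2h, dtype=float)            # (n,)
        self.W = np.asarray(weight_mat, dtype=float)       # (n, 4)
        self.M = np.asarray(month_mat, dtype=int)          # (n, 4), 0-based
        self.year_idx = np.asarray(year_idx, dtype=int)    # (n,)
        self.n_years = int(self.year_idx.max()) + 1
        self.pdx_pred = np.asarray(pdx_pred, dtype=float)  # (12,)
        self.pdx_mvar = float(pdx_mvar)
        self.src_preds = np.asarray(src_preds, dtype=float)  # (57, 12)
        self.src_mvar = np.asarray(src_mvar, dtype=float)    # (57,)
        self.prior = prior
        self.log_pi = prior.log_probs                        # (58,)
        self.cut = np.asarray(cut_draws, dtype=float)        # (K, 3): a, b, Δ
        self.lo, self.hi = time_bounds
        self.log_lo, self.log_hi = np.log(self.lo), np.log(self.hi)
        self.convention = convention
        self.n = self.d2h.size
        self.n_src = self.src_preds.shape[0]
        self.year_counts = np.bincount(self.year_idx, minlength=self.n_years)

    # -- end-members for one iteration's truth draw ------------------------
    def _draw_end_members(self, delta: float, rng: np.random.Generator):
        t_pdx = self.pdx_pred + np.sqrt(self.pdx_mvar) * rng.standard_normal(12)
        t_src = (self.src_preds
                 + np.sqrt(self.src_mvar)[:, None] * rng.standard_normal(
                     self.src_preds.shape))
        em_pdx = delta + (self.W * t_pdx[self.M]).sum(axis=1)          # (n,)
        em_src = delta + np.einsum("nj,snj->ns", self.W, t_src[:, self.M])
        return em_pdx, em_src                                           # (n,57)

    # -- marginal likelihood pieces ---------------------------------------
    def _mu_matrix(self, p: np.ndarray, em_pdx: np.ndarray,
                   em_src: np.ndarray, mu_comp: float) -> np.ndarray:
        em_full = np.concatenate(
            [em_src, np.full((self.n, 1), mu_comp)], axis=1)           # (n, 58)
        return p[:, None] * em_pdx[:, None] + (1 - p)[:, None] * em_full

    def _var_matrix(self, p: np.ndarray, s_pdx: float, s_src: float,
                    s_comp: float) -> np.ndarray:
        var = np.empty((self.n, self.n_src + 1))
        var[:, :-1] = (p * s_pdx ** 2 + (1 - p) * s_src ** 2)[:, None]
        var[:, -1] = p * s_pdx ** 2 + (1 - p) * s_comp ** 2
        return var

    def _marginal(self, mu: np.ndarray, var: np.ndarray,
                  return_weights: bool = False):
        log_terms = (self.log_pi[None, :] - 0.5 * (_LOG_2PI + np.log(var))
                     - 0.5 * (self.d2h[:, None] - mu) ** 2 / var)
        m = log_terms.max(axis=1, keepdims=True)
        w = np.exp(log_terms - m)
        s = w.sum(axis=1)
        loglik = m[:, 0] + np.log(s)                                   # (n,)
        if return_weights:
            return loglik, w / s[:, None]
        return loglik

    def _loglik_vec(self, p, em_pdx, em_src, mu_comp, s_pdx, s_src, s_comp):
        mu = self._mu_matrix(p, em_pdx, em_src, mu_comp)
        var = self._var_matrix(p, s_pdx, s_src, s_comp)
        return self._marginal(mu, var)

    # -- engine protocol ---------------------------------------------------
    def init_state(self, rng: np.random.Generator, dispersion: float) -> dict:
        # anchor starting times in the likelihood basin: invert the mixing
        # fraction implied by each δ²H against plug-in end members, then
        # overdisperse. Without this, diffuse starts inflate the residual
        # SDs during burn-in and chains settle in a flat-likelihood mode.
        a0, b0, delta0 = self.cut.mean(axis=0)
        em_pdx0 = delta0 + (self.W * self.pdx_pred[self.M]).sum(axis=1)
        mean_src_pred = self.src_preds.mean(axis=0)            # (12,)
        em_src0 = delta0 + (self.W * mean_src_pred[self.M]).sum(axis=1)
        p_hat = np.clip((self.d2h - em_src0) / (em_pdx0 - em_src0), 0.02, 0.98)
        t_hat = np.clip((p_hat - a0) / b0 + 14.0, self.lo * 1.2, self.hi * 0.9)
        log_t = np.log(t_hat) + dispersion * rng.normal(0, 0.5, self.n)
        log_t = np.clip(log_t, self.log_lo + 0.05, self.log_hi - 0.05)
        mu_t = np.array([
            log_t[self.year_idx == y].mean() if self.year_counts[y] else 2.0
            for y in range(self.n_years)])
        state = {
            "log_times": log_t,
            "mu_time": mu_t + dispersion * rng.normal(0, 0.5, self.n_years),
            "sigma_time": np.clip(
                np.exp(rng.normal(0, 0.3 * dispersion, self.n_years)), 0.1, 5.0),
            "sigma_pdx": float(np.clip(rng.uniform(3, 15) *
                                       np.exp(0.2 * dispersion * rng.standard_normal()),
                                       0.5, 99.0)),
            "sigma_source": float(np.clip(rng.uniform(3, 15) *
                                          np.exp(0.2 * dispersion * rng.standard_normal()),
                                          0.5, 99.0)),
            "sigma_composite": float(np.clip(rng.uniform(5, 25) *
                                             np.exp(0.2 * dispersion * rng.standard_normal()),
                                             0.5, 99.0)),
            "mu_comp": float(self.d2h.max() + dispersion * rng.normal(0, 10)),
            "cut_perm": rng.permutation(self.cut.shape[0]),
            "_t_scale": 0.5,
            "_t_accept": 0.0,
            "_t_count": 0,
            "_weights": np.full((self.n, self.n_src + 1),
                                1.0 / (self.n_src + 1)),
            "_region_probs": np.full(self.n_src + 1, 1.0 / (self.n_src + 1)),
            "_loglik": 0.0,
        }
        return state

    def _cut_draw(self, state: dict, iteration: int) -> tuple[float, float, float]:
        k = state["cut_perm"][iteration % state["cut_perm"].size]
        a, b, delta = self.cut[k]
        return float(a), float(b), float(delta)

    def step(self, state: dict, rng: np.random.Generator,
             iteration: int, adapting: bool) -> None:
        a, b, delta = self._cut_draw(state, iteration)
        em_pdx, em_src = self._draw_end_members(delta, rng)

        log_t = state["log_times"]
        mu_y = state["mu_time"][self.year_idx]
        sig_y = state["sigma_time"][self.year_idx]
        s_pdx, s_src, s_comp = (state["sigma_pdx"], state["sigma_source"],
                                state["sigma_composite"])
        mu_comp = state["mu_comp"]

        # --- latent times: reflected random walk on log(time) ------------
        p_cur = q_fraction(a, b, np.exp(log_t), self.convention)
        ll_cur = self._loglik_vec(p_cur, em_pdx, em_src, mu_comp,
                                  s_pdx, s_src, s_comp)
        # target in θ = log t is Normal(μ_yr, σ_yr) × likelihood (the
        # lognormal Jacobian cancels; the truncation constant is common)
        lp_cur = ll_cur - 0.5 * ((log_t - mu_y) / sig_y) ** 2

        prop = log_t + state["_t_scale"] * rng.standard_normal(self.n)
        for _ in range(4):  # reflect into (log lo, log hi)
            prop = np.where(prop > self.log_hi, 2 * self.log_hi - prop, prop)
            prop = np.where(prop < self.log_lo, 2 * self.log_lo - prop, prop)
        p_new = q_fraction(a, b, np.exp(prop), self.convention)
        ll_new = self._loglik_vec(p_new, em_pdx, em_src, mu_comp,
                                  s_pdx, s_src, s_comp)
        lp_new = ll_new - 0.5 * ((prop - mu_y) / sig_y) ** 2
        accept = np.log(rng.uniform(size=self.n)) < lp_new - lp_cur
        log_t[:] = np.where(accept, prop, log_t)
        if adapting:
            state["_t_accept"] += accept.mean()
            state["_t_count"] += 1
            if state["_t_count"] == 50:
                rate = state["_t_accept"] / 50
                state["_t_scale"] = float(np.clip(
                    state["_t_scale"] * np.exp(0.7 * (rate - 0.3)), 0.02, 3.0))
                state["_t_accept"] = 0.0
                state["_t_count"] = 0

        times = np.exp(log_t)
        p = q_fraction(a, b, times, self.convention)

        # --- year-level time hyperparameters ------------------------------
        for y in range(self.n_years):
            mask = self.year_idx == y
            lt = log_t[mask]
            mu0, sig0 = state["mu_time"][y], state["sigma_time"][y]

            def year_lp(mu: float, sig: float, lt=lt) -> float:
                if lt.size == 0:
                    return 0.0
                z_hi = (self.log_hi - mu) / sig
                z_lo = (self.log_lo - mu) / sig
                mass = ndtr(z_hi) - ndtr(z_lo)
                if mass <= 0:
                    return -np.inf
                return float(-0.5 * np.sum(((lt - mu) / sig) ** 2)
                             - lt.size * (np.log(sig) + np.log(mass)))

            # independence proposal centred on the empirical mean of the
            # year's log-times (the untruncated conjugate conditional);
            # the MH correction accounts for the truncation constant
            if lt.size:
                prop_mean = float(lt.mean())
                prop_sd = sig0 / math.sqrt(lt.size)
                mu_prop = prop_mean + prop_sd * rng.standard_normal()
                log_q = (-0.5 * ((mu_prop - prop_mean) / prop_sd) ** 2
                         + 0.5 * ((mu0 - prop_mean) / prop_sd) ** 2)
            else:
                mu_prop = mu0 + 0.3 * rng.standard_normal()
                log_q = 0.0
            lr = (year_lp(mu_prop, sig0) - year_lp(mu0, sig0)
                  - 0.5 * (mu_prop ** 2 - mu0 ** 2) / _MU_TIME_PRIOR_VAR
                  - log_q)
            if np.log(rng.uniform()) < lr:
                state["mu_time"][y] = mu_prop
                mu0 = mu_prop

            state["sigma_time"][y] = sigma_logscale_update(
                sig0, lambda s, mu0=mu0: year_lp(mu0, s), rng)

        # --- residual SDs and composite end-member ------------------------
        # μ matrix is fixed while the σs move; precompute squared deviations
        mu_mat = self._mu_matrix(p, em_pdx, em_src, mu_comp)
        dev2 = (self.d2h[:, None] - mu_mat) ** 2

        def total_ll(s_pdx_, s_src_, s_comp_) -> float:
            var = self._var_matrix(p, s_pdx_, s_src_, s_comp_)
            log_terms = (self.log_pi[None, :] - 0.5 * (_LOG_2PI + np.log(var))
                         - 0.5 * dev2 / var)
            m = log_terms.max(axis=1, keepdims=True)
            return float(np.sum(m[:, 0]
                                + np.log(np.exp(log_terms - m).sum(axis=1))))

        state["sigma_pdx"] = sigma_logscale_update(
            s_pdx, lambda s: total_ll(s, state["sigma_source"],
                                      state["sigma_composite"]), rng)
        state["sigma_source"] = sigma_logscale_update(
            state["sigma_source"],
            lambda s: total_ll(state["sigma_pdx"], s,
                               state["sigma_composite"]), rng)
        state["sigma_composite"] = sigma_logscale_update(
            state["sigma_composite"],
            lambda s: total_ll(state["sigma_pdx"], state["sigma_source"], s),
            rng)

        var = self._var_matrix(p, state["sigma_pdx"], state["sigma_source"],
                               state["sigma_composite"])

        def comp_lp(mc: float) -> float:
            mu_c = p * em_pdx + (1 - p) * mc
            d2 = dev2.copy()
            d2[:, -1] = (self.d2h - mu_c) ** 2
            log_terms = (self.log_pi[None, :] - 0.5 * (_LOG_2PI + np.log(var))
                         - 0.5 * d2 / var)
            m = log_terms.max(axis=1, keepdims=True)
            ll = float(np.sum(m[:, 0]
                              + np.log(np.exp(log_terms - m).sum(axis=1))))
            return ll - 0.5 * mc ** 2 / _MU_COMP_PRIOR_VAR

        # mixture proposal: mostly local moves, occasional large jumps so the
        # weakly identified composite end-member can hop between modes
        mc_scale = 30.0 if rng.uniform() < 0.1 else 3.0
        mc_prop = mu_comp + mc_scale * rng.standard_normal()
        if np.log(rng.uniform()) < comp_lp(mc_prop) - comp_lp(mu_comp):
            state["mu_comp"] = mc_prop

        # --- final marginal for accumulators ------------------------------
        mu_mat = self._mu_matrix(p, em_pdx, em_src, state["mu_comp"])
        var = self._var_matrix(p, state["sigma_pdx"], state["sigma_source"],
                               state["sigma_composite"])
        loglik, weights = self._marginal(mu_mat, var, return_weights=True)
        state["_weights"] = weights
        state["_region_probs"] = weights.mean(axis=0)
        state["_loglik"] = float(loglik.sum())

    def tracked(self, state: dict) -> dict:
        return {
            "times": np.exp(state["log_times"]),
            "mu_time": state["mu_time"].copy(),
            "sigma_time": state["sigma_time"].copy(),
            "sigma_pdx": state["sigma_pdx"],
            "sigma_source": state["sigma_source"],
            "sigma_composite": state["sigma_composite"],
            "mu_comp": state["mu_comp"],
            "region_probs": state["_region_probs"].copy(),
            "loglik": state["_loglik"],
        }

    def accumulate(self, state: dict) -> dict:
        return {"source_probs": state["_weights"]}


@dataclass
class PdxPosterior:
    """Posterior for the monitored-site cohort.

    ``times_draws`` has shape (n_chains, n_kept, n_beetles);
    ``source_probs`` is the (n_beetles, n_regions) Monte-Carlo average of
    the normalized source weights; ``region_prob_draws`` the per-iteration
    beetle-averaged region probabilities, used for credible intervals.
    """

    posterior: ModelPosterior
    times_draws: np.ndarray
    source_probs: np.ndarray
    region_prob_draws: np.ndarray
    specimen_ids: list[str]
    years: np.ndarray
    year_labels: list[int]
    region_ids: list[str]
    prior: SourcePrior

    @property
    def time_mean(self) -> np.ndarray:
        return self.times_draws.reshape(-1, self.times_draws.shape[-1]).mean(axis=0)

    def time_ci(self) -> np.ndarray:
        flat = self.times_draws.reshape(-1, self.times_draws.shape[-1])
        return np.percentile(flat, [2.5, 97.5], axis=0)


def _prepare_cut_draws(turnover_post: TurnoverPosterior,
                       calibration: CalibrationPosterior,
                       max_draws: int = 2000) -> np.ndarray:
    """Stack stored upstream draws into (K, 3) rows of (a, b, Δ).

    (a, b) stay paired; Δ comes from an independent stage and is aligned by
    index. Draws are thinned evenly to at most ``max_draws`` rows.
    """
    k = min(turnover_post.a_draws.size, calibration.delta_draws.size)
    idx_ab = np.linspace(0, turnover_post.a_draws.size - 1,
                         min(k, max_draws)).astype(int)
    idx_d = np.linspace(0, calibration.delta_draws.size - 1,
                        min(k, max_draws)).astype(int)
    return np.column_stack([turnover_post.a_draws[idx_ab],
                            turnover_post.b_draws[idx_ab],
                            calibration.delta_draws[idx_d]])


def fit_pdx_model(specimens: Sequence[SpecimenRecord],
                  locations: Sequence[LocationRecord],
                  prior: SourcePrior,
                  turnover_post: TurnoverPosterior,
                  calibration: CalibrationPosterior,
                  mcmc_config: McmcConfig | None = None,
                  variance_factor: float | None = None,
                  time_bounds: tuple[float, float] = (0.5, 60.0),
                  window_days: int = 90,
                  convention: str = "shifted",
                  max_cut_draws: int = 2000) -> PdxPosterior:
    """Fit latent source and time-since-arrival for the monitored cohort.

    ``prior.region_ids`` must match location_ids of source-role locations;
    the single pdx-role location supplies the local end-member isoscape.
    """
    mcmc_config = mcmc_config or McmcConfig()
    pdx = [s for s in specimens if s.cohort == "pdx"]
    if not pdx:
        raise ValidationError("no monitored-site specimens supplied")
    loc_by_id = {loc.location_id: loc for loc in locations}
    pdx_loc = next((l for l in locations if l.role == "pdx"), None)
    if pdx_loc is None:
        raise ValidationError("locations must include one record with role 'pdx'")
    missing = [r for r in prior.region_ids if r not in loc_by_id]
    if missing:
        raise ValidationError(f"prior region(s) without a location: {missing}")

    if variance_factor is None:
        mat = np.array([loc.precip_monthly_pred for loc in locations
                        if loc.role != "pdx"])
        rho, _ = pairwise_month_correlations(mat)
        variance_factor = monthly_variance_factor(12, rho)

    d2h = np.array([s.d2h for s in pdx])
    ww = [window_weights(s.collection_date, window_days) for s in pdx]
    weight_mat = np.array([w for w, _ in ww])
    month_mat = np.array([m - 1 for _, m in ww])
    year_labels = sorted({s.year for s in pdx})
    year_pos = {y: i for i, y in enumerate(year_labels)}
    year_idx = np.array([year_pos[s.year] for s in pdx])

    src_locs = [loc_by_id[r] for r in prior.region_ids]
    src_preds = np.array([l.precip_monthly_pred for l in src_locs])
    src_mvar = np.array([variance_factor * l.precip_annual_var for l in src_locs])

    model = PdxModel(
        d2h=d2h, weight_mat=weight_mat, month_mat=month_mat, year_idx=year_idx,
        pdx_pred=np.array(pdx_loc.precip_monthly_pred),
        pdx_mvar=variance_factor * pdx_loc.precip_annual_var,
        src_preds=src_preds, src_mvar=src_mvar, prior=prior,
        cut_draws=_prepare_cut_draws(turnover_post, calibration, max_cut_draws),
        time_bounds=time_bounds, convention=convention)

    post = run_mcmc(model, mcmc_config)
    return PdxPosterior(
        posterior=post,
        times_draws=post.draws["times"],
        source_probs=post.accumulators["source_probs"],
        region_prob_draws=post.draws["region_probs"],
        specimen_ids=[s.specimen_id for s in pdx],
        years=np.array([s.year for s in pdx]),
        year_labels=year_labels,
        region_ids=list(prior.region_ids),
        prior=prior)
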