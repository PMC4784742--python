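"""Post-hoc descriptive analyses: regressions, trends, annual summaries.

These are the desk checks that accompany the Bayesian fits — the
voucher-vs-precipitation regression surface, the temporal trend in
monitored-site δ²H, annual time-since-arrival summaries, source
probability versus latitude, and the exponential decline in beetles per
inspected aircraft. All straight-line fits go through statsmodels
OLS/WLS.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .datatypes import (LocationRecord, SpecimenRecord, SurveillanceRecord,
                        ValidationError)
from .mixing import PdxPosterior, truncated_lognormal_mean

__all__ = ["RegressionResult", "ExpDeclineFit", "voucher_annual_regression",
           "annual_time_summary", "d2h_year_trend",
           "latitude_source_regression", "posterior_minus_prior_regression",
           "exp_decline_fit", "prior_robustness"]


@dataclass
class RegressionResult:
    """Slope/intercept summary of a straight-line fit."""

    slope: float
    slope_se: float
    intercept: float
    r_squared: float
    p_value: float
    weights_used: bool = False
    n: int = 0

    def __post_init__(self) -> None:
        if not -1e-9 <= self.r_squared <= 1 + 1e-9:
            raise ValidationError("r_squared must lie in [0, 1]")


def _linfit(x: np.ndarray, y: np.ndarray,
            weights: np.ndarray | None = None) -> RegressionResult:
    X = sm.add_constant(np.asarray(x, dtype=float))
    y = np.asarray(y, dtype=float)
    model = (sm.WLS(y, X, weights=weights) if weights is not None
             else sm.OLS(y, X))
    res = model.fit()
    r2 = float(res.rsquared)
    if not np.isfinite(r2):
        r2 = 0.0  # constant response: no variance to explain
    return RegressionResult(
        slope=float(res.params[1]), slope_se=float(res.bse[1]),
        intercept=float(res.params[0]), r_squared=r2,
        p_value=float(res.pvalues[1]), weights_used=weights is not None,
        n=int(y.size))


def voucher_annual_regression(vouchers: Sequence[SpecimenRecord],
                              locations: Sequence[LocationRecord]
                              ) -> RegressionResult:
    """OLS of voucher δ²H on the annual-mean precipitation δ²H of its site.

    The annual mean is the unweighted mean of the 12 monthly predictions.
    """
    vouchers = [v for v in vouchers if v.cohort == "voucher"]
    loc_by_id = {l.location_id: l for l in locations}
    sites = {v.location_id for v in vouchers}
    if len(sites) < 3:
        raise ValidationError(
            f"need >= 3 distinct voucher sites for a regression, got {len(sites)}")
    annual = {s: float(np.mean(loc_by_id[s].precip_monthly_pred)) for s in sites}
    x = np.array([annual[v.location_id] for v in vouchers])
    y = np.array([v.d2h for v in vouchers])
    return _linfit(x, y)


def annual_time_summary(pdx_post: PdxPosterior) -> pd.DataFrame:
    """Per-year posterior of the mean time-since-arrival (days).

    Two summaries per year: ``mean``/``ci_*`` are the posterior of the
    across-beetle average of the latent times (the cohort average actually
    caught that year); ``hyper_mean``/``hyper_ci_*`` are the posterior of
    the truncated-lognormal population mean implied by the year-level
    hyperparameters (the truncated form keeps the summary inside the
    0.5–60 day support even for diffuse hyperparameter draws).
    """
    flat_times = pdx_post.times_draws.reshape(-1, pdx_post.times_draws.shape[-1])
    mu = pdx_post.posterior.pooled("mu_time")
    sig = pdx_post.posterior.pooled("sigma_time")
    hyper = truncated_lognormal_mean(mu, sig)
    rows = []
    for k, year in enumerate(pdx_post.year_labels):
        mask = pdx_post.years == year
        per_draw = flat_times[:, mask].mean(axis=1)
        lo, hi = np.percentile(per_draw, [2.5, 97.5])
        hlo, hhi = np.percentile(hyper[:, k], [2.5, 97.5])
        rows.append({"year": year, "n_beetles": int(mask.sum()),
                     "mean": per_draw.mean(), "ci_lower": lo, "ci_upper": hi,
                     "hyper_mean": hyper[:, k].mean(),
                     "hyper_ci_lower": hlo, "hyper_ci_upper": hhi})
    return pd.DataFrame(rows)


def d2h_year_trend(pdx_specimens: Sequence[SpecimenRecord]) -> RegressionResult:
    """OLS of monitored-site δ²H on collection year (‰ per year)."""
    pdx = [s for s in pdx_specimens if s.cohort == "pdx"]
    if len(pdx) < 3:
        raise ValidationError("need >= 3 monitored-site specimens")
    return _linfit(np.array([s.year for s in pdx], dtype=float),
                   np.array([s.d2h for s in pdx]))


def latitude_source_regression(source_probs: np.ndarray,
                               latitudes: np.ndarray,
                               ci_widths: np.ndarray | None = None,
                               weighted: bool = True) -> RegressionResult:
    """Mean posterior source probability regressed on region latitude.

    ``source_probs`` holds one probability per candidate region (the
    composite region, which has no latitude, is excluded by the caller).
    When ``weighted``, each region is weighted by the inverse of its 95%
    credible-interval width (read as 1/(upper − lower)), so better-resolved
    regions count more.
    """
    probs = np.asarray(source_probs, dtype=float)
    lats = np.asarray(latitudes, dtype=float)
    if probs.size != lats.size:
        raise ValidationError("one probability and one latitude per region")
    weights = None
    if weighted:
        if ci_widths is None:
            raise ValidationError("weighted regression requires ci_widths")
        w = np.asarray(ci_widths, dtype=float)
        if np.any(w <= 0):
            raise ValidationError("credible-interval widths must be > 0")
        weights = 1.0 / w
    return _linfit(lats, probs, weights)


def region_summary(pdx_post: PdxPosterior,
                   latitudes: dict[str, float]) -> pd.DataFrame:
    """Per-region beetle-averaged posterior probability with 95% CI."""
    draws = pdx_post.region_prob_draws.reshape(-1,
                                               pdx_post.region_prob_draws.shape[-1])
    lo, hi = np.percentile(draws, [2.5, 97.5], axis=0)
    mean = draws.mean(axis=0)
    ids = pdx_post.region_ids + ["composite"]
    return pd.DataFrame({
        "region_id": ids,
        "latitude": [latitudes.get(r, np.nan) for r in ids],
        "prior_prob": pdx_post.prior.probs,
        "posterior_prob": mean,
        "ci_lower": lo, "ci_upper": hi,
        "ci_width": hi - lo,
    })


def posterior_minus_prior_regression(posterior_probs: np.ndarray,
                                     prior_probs: np.ndarray,
                                     latitudes: np.ndarray) -> RegressionResult:
    """OLS of (posterior − prior) source probability on latitude."""
    post = np.asarray(posterior_probs, dtype=float)
    pri = np.asarray(prior_probs, dtype=float)
    return _linfit(np.asarray(latitudes, dtype=float), post - pri)


@dataclass
class ExpDeclineFit:
    """Log-linear fit of beetles-per-aircraft against year."""

    rate_percent: float           # 100·(1 − exp(slope)), % decline per year
    regression: RegressionResult
    n_used: int
    n_dropped_zero: int
    rate_percent_pseudocount: float | None = None


def exp_decline_fit(surveillance: Sequence[SurveillanceRecord]) -> ExpDeclineFit:
    """Annual decline rate of beetles per inspected aircraft.

    Log-linear OLS on the positive observations; years with missing values
    are skipped. When zero counts are present, a sensitivity variant
    replacing zeros by half the smallest positive value is also reported.
    """
    pairs = [(r.year, r.beetles_per_aircraft) for r in surveillance
             if r.beetles_per_aircraft is not None]
    if len(pairs) < 3:
        raise ValidationError("need >= 3 surveillance years with data")
    years = np.array([y for y, _ in pairs], dtype=float)
    vals = np.array([v for _, v in pairs], dtype=float)
    pos = vals > 0
    reg = _linfit(years[pos], np.log(vals[pos]))
    rate = 100.0 * (1.0 - np.exp(reg.slope))
    pseudo_rate = None
    if np.any(~pos):
        floor = vals[pos].min() / 2.0
        reg2 = _linfit(years, np.log(np.maximum(vals, floor)))
        pseudo_rate = 100.0 * (1.0 - np.exp(reg2.slope))
    return ExpDeclineFit(rate_percent=float(rate), regression=reg,
                         n_used=int(pos.sum()),
                         n_dropped_zero=int((~pos).sum()),
                         rate_percent_pseudocount=pseudo_rate)


def prior_robustness(time_means_flat: np.ndarray,
                     time_means_traffic: np.ndarray) -> RegressionResult:
    """Agreement of per-beetle posterior-mean times across prior choices.

    OLS of the flat-prior means on the traffic-prior means; slope and R²
    near 1 indicate the time estimates are robust to the source prior.
    """
    a = np.asarray(time_means_flat, dtype=float)
    b = np.asarray(time_means_traffic, dtype=float)
    if a.size != b.size:
        raise ValidationError("per-beetle mean arrays must align")
    return _linfit(b, a)
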