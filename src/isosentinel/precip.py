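"""Berkson measurement model for the true monthly precipitation δ²H.

The precipitation calculator supplies, per location, twelve monthly δ²H
predictions and one variance attached to the *annual mean* prediction.
The model treats the unknown true monthly value as normally distributed
around the monthly prediction (a Berkson-type error structure), so the
annual-mean variance must be scaled up to a monthly variance.

Writing the annual mean as the mean of N = 12 correlated monthly values
with common variance σ² and pairwise correlations ρ_ij,

    Var(x̄) = (N·σ² + 2·σ²·Σ_{i<j} ρ_ij) / N²,

so σ² = Var(x̄) · N² / (N + 2·Σρ).  With the strong inter-month
correlations typical of precipitation isoscapes (mean ρ ≈ 0.96) the factor
is only slightly above 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .datatypes import LocationRecord, ValidationError

__all__ = [
    "PrecipTruth",
    "pairwise_month_correlations",
    "monthly_variance_factor",
    "monthly_variances",
    "sample_precip_truth",
    "correlation_diagnostics",
]


@dataclass
class PrecipTruth:
    """A latent true monthly precipitation δ²H with its Berkson variance."""

    location_id: str
    month: int
    d2h_true: float
    monthly_var: float


def pairwise_month_correlations(monthly_matrix: np.ndarray) -> tuple[np.ndarray, float]:
    """Pearson correlations between all month pairs across locations.

    ``monthly_matrix`` has shape (n_locations, 12). Returns the C(12,2) = 66
    upper-triangle coefficients (ordered (1,2), (1,3), ..., (11,12)) and
    their mean.
    """
    x = np.asarray(monthly_matrix, dtype=float)
    if x.ndim != 2 or x.shape[1] != 12:
        raise ValidationError(f"expected a (n_locations, 12) matrix, got {x.shape}")
    if x.shape[0] < 3:
        raise ValidationError("need at least 3 locations to estimate correlations")
    if not np.all(np.isfinite(x)):
        raise ValidationError("monthly matrix contains non-finite values")
    sd = x.std(axis=0)
    if np.any(sd == 0):
        months = [m + 1 for m in np.nonzero(sd == 0)[0]]
        raise ValidationError(
            f"correlation undefined: month column(s) {months} are constant across locations"
        )
    corr = np.corrcoef(x, rowvar=False)
    iu, ju = np.triu_indices(12, k=1)
    rho = corr[iu, ju]
    return rho, float(rho.mean())


def monthly_variance_factor(n_months: int, correlations: Sequence[float]) -> float:
    """Scaling from annual-mean variance to monthly variance: N²/(N + 2·Σρ)."""
    n = int(n_months)
    if n < 2:
        raise ValidationError("n_months must be >= 2")
    rho = np.asarray(correlations, dtype=float)
    expected = n * (n - 1) // 2
    if rho.size != expected:
        raise ValidationError(
            f"expected {expected} = C({n},2) correlations, got {rho.size}"
        )
    denom = n + 2.0 * rho.sum()
    if denom <= 0:
        raise ValidationError(
            f"invalid correlation structure: N + 2·Σρ = {denom} <= 0"
        )
    return n * n / denom


def monthly_variances(locations: Sequence[LocationRecord],
                      factor: float) -> dict[str, float]:
    """Per-location monthly Berkson variance = factor × annual variance."""
    return {loc.location_id: factor * loc.precip_annual_var for loc in locations}


def sample_precip_truth(location: LocationRecord, month: int,
                        rng: np.random.Generator, monthly_var: float) -> float:
    """One draw of the latent true δ²H for (location, month).

    Inside the samplers these truths are re-drawn every iteration, making
    the Berkson uncertainty a full part of the posterior rather than a
    plug-in value.
    """
    if not 1 <= month <= 12:
        raise ValidationError(f"month must be in 1..12, got {month}")
    pred = location.precip_monthly_pred[month - 1]
    if monthly_var == 0:
        return pred
    return float(rng.normal(pred, np.sqrt(monthly_var)))


def correlation_diagnostics(locations: Sequence[LocationRecord]) -> pd.DataFrame:
    """Correlation table for the non-monitored locations, as a diagnostics frame.

    The monitored (pdx) site is excluded: the factor is estimated from the
    source and voucher isoscape locations.
    """
    mat = np.array([loc.precip_monthly_pred for loc in locations
                    if loc.role != "pdx"])
    rho, mean_rho = pairwise_month_correlations(mat)
    iu, ju = np.triu_indices(12, k=1)
    df = pd.DataFrame({"month_i": iu + 1, "month_j": ju + 1, "rho": rho})
    df.attrs["mean_rho"] = mean_rho
    df.attrs["factor"] = monthly_variance_factor(12, rho)
    return df
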