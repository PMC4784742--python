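"""Synthetic data with the statistical structure the analysis assumes.

Generates the full input set — an isoscape of monthly precipitation δ²H
predictions with strong inter-month correlation, voucher specimens with a
constant beetle-precipitation offset, a lag-ramp-plateau turnover
experiment, a monitored-site capture cohort with known latent source and
time-since-arrival, flight-traffic counts, and a surveillance series —
together with the latent truth tables needed for parameter-recovery
scoring. All randomness flows from the single scenario seed.

The default scenario is sized like the published study (57 candidate
source regions plus a composite, 15 voucher sites, ~100 vouchers, 101
monitored-site beetles, 62 turnover beetles over six weekly harvests) with
a precipitation gradient that is high in the southeast and declines to the
northwest, year-level mean times that fall from ~40 days to under a week
across the sampling years, and an inter-month correlation target of 0.96.
"""

from __future__ import annotations

import datetime as _dt
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import (LocationRecord, SpecimenRecord, SurveillanceRecord,
                        TrafficRecord, TurnoverObservation, ValidationError)
from .io import InputBundle
from .mixing import build_source_prior, window_weights
from .precip import monthly_variance_factor, pairwise_month_correlations
from .turnover import q_fraction, turnover_mean

__all__ = ["ScenarioSpec", "SyntheticDataset", "simulate_precip",
           "simulate_vouchers", "simulate_turnover", "simulate_pdx",
           "simulate_traffic", "simulate_surveillance", "simulate_all"]


def _default_time_mu() -> dict[int, float]:
    # year-level lognormal location parameters: long residence early,
    # rapid capture in later years
    return {2007: math.log(35.0), 2008: math.log(44.0), 2009: math.log(32.0),
            2010: math.log(30.0), 2011: math.log(20.0), 2012: math.log(6.0),
            2013: math.log(5.0), 2014: math.log(7.0)}


@dataclass
class ScenarioSpec:
    """Ground-truth parameters and sizes for one synthetic study."""

    n_sources: int = 57
    n_voucher_sites: int = 15
    n_vouchers: int = 100
    n_pdx_beetles: int = 101
    turnover_counts: tuple[int, ...] = (11, 11, 10, 10, 10, 10)
    turnover_days: tuple[float, ...] = (0.0, 7.0, 14.0, 21.0, 28.0, 35.0)
    delta_true: float = -48.0
    a_true: float = 0.03
    b_true: float = 0.047
    init_true: float = -60.0
    final_true: float = -110.0
    sigma_vs: float = 6.0
    sigma_exp: tuple[float, float, float] = (4.0, 6.0, 4.0)
    sigma_pdx: float = 8.0
    sigma_source: float = 8.0
    sigma_composite: float = 12.0
    mu_comp_true: float = -30.0  # above every source end-member, as the
    # composite region exists to explain values no candidate source can reach
    precip_gradient: float = -3.0      # ‰ per degree latitude
    precip_lon_gradient: float = 1.2   # ‰ per degree longitude (east positive)
    precip_intercept: float = 65.0     # ‰ at latitude 0, longitude −85
    seasonal_amplitude: float = 12.0   # ‰, summer-peaking sinusoid
    inter_month_rho_target: float = 0.961
    annual_var: float = 9.0            # ‰², calculator-style Berkson variance
    time_mu_by_year: dict[int, float] = field(default_factory=_default_time_mu)
    time_sigma: float = 0.5            # log-scale SD, shared across years
    time_bounds: tuple[float, float] = (0.5, 60.0)
    composite_mass: float = 0.20
    source_distribution: np.ndarray | None = None
    window_days: int = 90
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_sources", "n_voucher_sites", "n_vouchers",
                     "n_pdx_beetles"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")
        if not 0.0 < self.inter_month_rho_target < 1.0:
            raise ValidationError("inter_month_rho_target must be in (0, 1)")
        if len(self.turnover_counts) != len(self.turnover_days):
            raise ValidationError("turnover_counts and turnover_days must align")
        if self.source_distribution is not None:
            sd = np.asarray(self.source_distribution, dtype=float)
            if sd.size != self.n_sources + 1 or not np.isclose(sd.sum(), 1.0):
                raise ValidationError(
                    "source_distribution must have n_sources+1 entries summing to 1")

    @property
    def years(self) -> list[int]:
        return sorted(self.time_mu_by_year)


@dataclass
class SyntheticDataset:
    """Inputs plus latent truth tables for recovery scoring."""

    spec: ScenarioSpec
    inputs: InputBundle
    precip_truth: pd.DataFrame     # location_id, month, d2h_true
    voucher_truth: pd.DataFrame    # specimen_id, month_true
    turnover_truth: pd.DataFrame   # specimen_id, days, mean_true
    pdx_truth: pd.DataFrame        # specimen_id, time_true, source_true, p_true
    traffic_prior: np.ndarray      # π used to draw sources (composite last)


def _seasonal(amplitude: float) -> np.ndarray:
    months = np.arange(1, 13)
    return amplitude * np.cos(2 * np.pi * (months - 7) / 12.0)


def simulate_precip(spec: ScenarioSpec,
                    rng: np.random.Generator) -> tuple[list[LocationRecord],
                                                       pd.DataFrame]:
    """Isoscape of monthly predictions plus a latent-truth table.

    Monthly prediction = latitudinal trend + shared seasonal sinusoid +
    site-month noise, with the noise scale chosen so the realized mean
    inter-month correlation across non-monitored sites matches the target.
    The latent true monthly values are drawn around the predictions with
    the scaled (monthly) Berkson variance, mirroring the measurement model.
    """
    if spec.seasonal_amplitude == 0:
        raise ValidationError(
            "degenerate scenario: zero seasonal amplitude makes all months "
            "identical and the inter-month correlation structure undefined")

    # candidate sources sit in the east; voucher sites span the continent;
    # the monitored site is in the far northwest, so its end-member falls
    # below every candidate source, as in the real isoscape
    src_lat = np.sort(rng.uniform(28.0, 45.0, spec.n_sources))[::-1]
    src_lon = rng.uniform(-93.0, -70.0, spec.n_sources)
    vs_lat = np.sort(rng.uniform(33.0, 47.0, spec.n_voucher_sites))
    vs_lon = rng.uniform(-115.0, -75.0, spec.n_voucher_sites)
    pdx_lat, pdx_lon = 45.6, -122.6

    ids = ([f"S{i+1:02d}" for i in range(spec.n_sources)]
           + [f"V{i+1:02d}" for i in range(spec.n_voucher_sites)]
           + ["PDX"])
    roles = (["source"] * spec.n_sources
             + ["voucher_site"] * spec.n_voucher_sites + ["pdx"])
    lats = np.concatenate([src_lat, vs_lat, [pdx_lat]])
    lons = np.concatenate([src_lon, vs_lon, [pdx_lon]])

    base = (spec.precip_intercept + spec.precip_gradient * lats
            + spec.precip_lon_gradient * (lons + 85.0))
    # site-month noise scaled so ρ = Var(base)/(Var(base)+σ²) hits the target
    var_base = base[:-1].var()
    rho = spec.inter_month_rho_target
    noise_sd = math.sqrt(var_base * (1.0 - rho) / rho)
    preds = (base[:, None] + _seasonal(spec.seasonal_amplitude)[None, :]
             + noise_sd * rng.standard_normal((lats.size, 12)))

    ann_var = spec.annual_var * rng.uniform(0.7, 1.3, lats.size)
    locations = [
        LocationRecord(location_id=i, latitude=float(lat), role=role,
                       precip_monthly_pred=tuple(row),
                       precip_annual_var=float(av))
        for i, lat, role, row, av in zip(ids, lats, roles, preds, ann_var)
    ]

    corr_mat = preds[:-1]  # non-monitored sites, as in the analysis
    rhos, _ = pairwise_month_correlations(corr_mat)
    factor = monthly_variance_factor(12, rhos)
    truths = preds + np.sqrt(factor * ann_var)[:, None] * rng.standard_normal(
        preds.shape)
    truth_df = pd.DataFrame({
        "location_id": np.repeat(ids, 12),
        "month": np.tile(np.arange(1, 13), len(ids)),
        "d2h_true": truths.ravel(),
    })
    return locations, truth_df


def _truth_lookup(truth_df: pd.DataFrame) -> dict[str, np.ndarray]:
    return {loc: g.sort_values("month")["d2h_true"].to_numpy()
            for loc, g in truth_df.groupby("location_id")}


def simulate_vouchers(spec: ScenarioSpec, locations: list[LocationRecord],
                      precip_truth: pd.DataFrame,
                      rng: np.random.Generator
                      ) -> tuple[list[SpecimenRecord], pd.DataFrame]:
    """Voucher specimens: Δ + true site-month precipitation + noise."""
    truth = _truth_lookup(precip_truth)
    sites = [l for l in locations if l.role == "voucher_site"]
    specimens, rows = [], []
    for i in range(spec.n_vouchers):
        site = sites[int(rng.integers(len(sites)))]
        month = int(rng.integers(1, 13))
        d2h = (spec.delta_true + truth[site.location_id][month - 1]
               + spec.sigma_vs * rng.standard_normal())
        sid = f"VCH{i+1:03d}"
        specimens.append(SpecimenRecord(
            specimen_id=sid, cohort="voucher", location_id=site.location_id,
            collection_date=_dt.date(2012, month, 15), d2h=float(d2h)))
        rows.append({"specimen_id": sid, "month_true": month,
                     "site": site.location_id})
    return specimens, pd.DataFrame(rows)


def simulate_turnover(spec: ScenarioSpec, rng: np.random.Generator
                      ) -> tuple[list[TurnoverObservation], pd.DataFrame]:
    """Weekly harvests with group-specific residual noise; truth recorded."""
    obs, rows = [], []
    i = 0
    for day, count in zip(spec.turnover_days, spec.turnover_counts):
        mean = float(turnover_mean(day, spec.init_true, spec.final_true,
                                   spec.a_true, spec.b_true))
        for _ in range(count):
            i += 1
            group = ("pre" if day <= 14 else "post" if day >= 35 else "ramp")
            sig = spec.sigma_exp[("pre", "ramp", "post").index(group)]
            d2h = mean + sig * rng.standard_normal()
            sid = f"EXP{i:03d}"
            obs.append(TurnoverObservation(
                specimen_id=sid, days_since_relocation=day, tissue="whole",
                d2h=float(d2h)))
            rows.append({"specimen_id": sid, "days": day, "mean_true": mean})
    return obs, pd.DataFrame(rows)


def simulate_traffic(spec: ScenarioSpec, locations: list[LocationRecord],
                     rng: np.random.Generator) -> list[TrafficRecord]:
    """Annual flight counts per source region (lognormal across regions)."""
    return [
        TrafficRecord(source_region_id=loc.location_id, latitude=loc.latitude,
                      flights_per_year=float(np.round(
                          rng.lognormal(mean=6.0, sigma=1.0))))
        for loc in locations if loc.role == "source"
    ]


def _truncated_lognormal(mu: float, sigma: float,
                         bounds: tuple[float, float], size: int,
                         rng: np.random.Generator) -> np.ndarray:
    from scipy.special import ndtr, ndtri
    lo = ndtr((math.log(bounds[0]) - mu) / sigma)
    hi = ndtr((math.log(bounds[1]) - mu) / sigma)
    u = rng.uniform(lo, hi, size)
    return np.exp(mu + sigma * ndtri(u))


def simulate_pdx(spec: ScenarioSpec, locations: list[LocationRecord],
                 precip_truth: pd.DataFrame, traffic: list[TrafficRecord],
                 rng: np.random.Generator
                 ) -> tuple[list[SpecimenRecord], pd.DataFrame, np.ndarray]:
    """Monitored-site captures generated from the mixing model itself.

    Each beetle draws a source region (traffic-weighted unless the spec
    overrides the distribution), a capture year and date, a truncated-
    lognormal time-since-arrival, the implied mixing fraction, and a δ²H
    from the mixture with the matching variance structure.
    """
    truth = _truth_lookup(precip_truth)
    if spec.source_distribution is not None:
        pi = np.asarray(spec.source_distribution, dtype=float)
    else:
        pi = build_source_prior(traffic, "traffic", spec.composite_mass).probs
    src_ids = [t.source_region_id for t in traffic]

    specimens, rows = [], []
    years = spec.years
    for i in range(spec.n_pdx_beetles):
        year = years[i % len(years)]
        date = (_dt.date(year, 6, 1)
                + _dt.timedelta(days=int(rng.integers(0, 122))))  # Jun-Sep
        t = float(_truncated_lognormal(spec.time_mu_by_year[year],
                                       spec.time_sigma, spec.time_bounds,
                                       1, rng)[0])
        p = float(q_fraction(spec.a_true, spec.b_true, t))
        src = int(rng.choice(pi.size, p=pi))

        w, months = window_weights(date, spec.window_days)
        em_pdx = spec.delta_true + float(truth["PDX"][months - 1] @ w)
        if src == pi.size - 1:  # composite region
            em_src = spec.mu_comp_true
            var_away = spec.sigma_composite ** 2
            src_label = "composite"
        else:
            em_src = spec.delta_true + float(truth[src_ids[src]][months - 1] @ w)
            var_away = spec.sigma_source ** 2
            src_label = src_ids[src]
        mean = p * em_pdx + (1 - p) * em_src
        var = p * spec.sigma_pdx ** 2 + (1 - p) * var_away
        d2h = mean + math.sqrt(var) * rng.standard_normal()

        sid = f"PDX{i+1:03d}"
        specimens.append(SpecimenRecord(
            specimen_id=sid, cohort="pdx", location_id="PDX",
            collection_date=date, d2h=float(d2h)))
        rows.append({"specimen_id": sid, "year": year, "time_true": t,
                     "source_true": src_label, "p_true": p})
    return specimens, pd.DataFrame(rows), pi


def simulate_surveillance(spec: ScenarioSpec, rng: np.random.Generator,
                          decline_rate: float = 0.15,
                          first_year: int = 1991, last_year: int = 2014,
                          y0: float = 2.0) -> list[SurveillanceRecord]:
    """Beetles-per-aircraft declining exponentially with mild noise."""
    records = []
    for year in range(first_year, last_year + 1):
        t = year - first_year
        bpa = y0 * (1 - decline_rate) ** t * math.exp(
            0.2 * rng.standard_normal())
        records.append(SurveillanceRecord(
            year=year, beetles_per_aircraft=float(bpa),
            beetles_trapped=float(rng.poisson(20)),
            acres_sprayed=float(rng.uniform(50, 300)),
            traps_deployed=float(100 if year < 2000 else 1000)))
    return records


def simulate_all(spec: ScenarioSpec) -> SyntheticDataset:
    """Generate the complete input bundle and truth tables from one seed."""
    rng = np.random.default_rng(spec.seed)
    locations, precip_truth = simulate_precip(spec, rng)
    vouchers, voucher_truth = simulate_vouchers(spec, locations, precip_truth, rng)
    turnover, turnover_truth = simulate_turnover(spec, rng)
    traffic = simulate_traffic(spec, locations, rng)
    pdx, pdx_truth, pi = simulate_pdx(spec, locations, precip_truth, traffic, rng)
    surveillance = simulate_surveillance(spec, rng)
    bundle = InputBundle(locations=locations, specimens=vouchers + pdx,
                         turnover=turnover, traffic=traffic,
                         surveillance=surveillance)
    return SyntheticDataset(spec=spec, inputs=bundle,
                            precip_truth=precip_truth,
                            voucher_truth=voucher_truth,
                            turnover_truth=turnover_truth,
                            pdx_truth=pdx_truth, traffic_prior=pi)
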