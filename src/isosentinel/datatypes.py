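"""Shared domain types for the isotope-assignment analysis.

All isotope values are hydrogen isotope ratios in delta notation
(δ²H, ‰ vs. VSMOW); variances are in ‰².
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from typing import Sequence

__all__ = [
    "SchemaError",
    "ValidationError",
    "LocationRecord",
    "SpecimenRecord",
    "TurnoverObservation",
    "TrafficRecord",
    "SurveillanceRecord",
    "validate_locations",
    "turnover_group",
]

# Turnover-experiment breakpoints (days since relocation): isotope values
# hold the source signature up to PRE_DAYS and are fully equilibrated with
# the new environment from POST_DAYS onward.
PRE_DAYS = 14.0
POST_DAYS = 35.0

LOCATION_ROLES = ("source", "voucher_site", "pdx")
COHORTS = ("voucher", "pdx")
TISSUES = ("whole", "wings", "elytra", "body")


class SchemaError(ValueError):
    """A tabular input is missing a required column or has the wrong shape."""


class ValidationError(ValueError):
    """A record violates a domain invariant."""


def _finite(x: float) -> bool:
    return x == x and abs(x) != float("inf")


@dataclass
class LocationRecord:
    """A site with monthly precipitation δ²H predictions and annual variance.

    ``precip_monthly_pred`` holds the 12 calculator-predicted monthly δ²H
    values (Jan..Dec); ``precip_annual_var`` is the variance attached to the
    annual mean prediction, later rescaled to a monthly variance.
    """

    location_id: str
    latitude: float
    role: str
    precip_monthly_pred: tuple[float, ...]
    precip_annual_var: float

    def __post_init__(self) -> None:
        if self.role not in LOCATION_ROLES:
            raise ValidationError(
                f"location {self.location_id}: role {self.role!r} not in {LOCATION_ROLES}"
            )
        self.precip_monthly_pred = tuple(float(v) for v in self.precip_monthly_pred)
        if len(self.precip_monthly_pred) != 12:
            raise SchemaError(
                f"location {self.location_id}: expected 12 monthly values, "
                f"got {len(self.precip_monthly_pred)}"
            )
        if not all(_finite(v) for v in self.precip_monthly_pred):
            raise ValidationError(f"location {self.location_id}: non-finite monthly δ²H")
        if not (_finite(self.precip_annual_var) and self.precip_annual_var > 0):
            raise ValidationError(
                f"location {self.location_id}: annual variance must be > 0, "
                f"got {self.precip_annual_var}"
            )


@dataclass
class SpecimenRecord:
    """One beetle's δ²H with its collection site/role and date."""

    specimen_id: str
    d2h: float
    location_id: str
    collection_date: _dt.date
    cohort: str

    def __post_init__(self) -> None:
        if self.cohort not in COHORTS:
            raise ValidationError(
                f"specimen {self.specimen_id}: cohort {self.cohort!r} not in {COHORTS}"
            )
        if not _finite(self.d2h):
            raise ValidationError(f"specimen {self.specimen_id}: non-finite δ²H")
        if isinstance(self.collection_date, str):
            self.collection_date = _dt.date.fromisoformat(self.collection_date)
        if self.cohort == "voucher" and not self.location_id:
            raise ValidationError(
                f"voucher specimen {self.specimen_id} must have a location_id"
            )
        if self.cohort == "pdx" and not isinstance(self.collection_date, _dt.date):
            raise ValidationError(
                f"pdx specimen {self.specimen_id} must have a valid collection date"
            )

    @property
    def year(self) -> int:
        return self.collection_date.year

    @property
    def month(self) -> int:
        return self.collection_date.month


def turnover_group(days: float) -> str:
    """Residual-variance group for a turnover observation.

    'pre' up to and including 14 days, 'post' from 35 days, 'ramp' between.
    Boundary days (exactly 14 / exactly 35) go to pre / post respectively —
    a convention, since the piecewise mean uses overlapping ≤/≥ there.
    """
    if days <= PRE_DAYS:
        return "pre"
    if days >= POST_DAYS:
        return "post"
    return "ramp"


@dataclass
class TurnoverObservation:
    """δ²H of one relocated beetle at a known number of days after the move."""

    specimen_id: str
    days_since_relocation: float
    d2h: float
    tissue: str = "whole"
    group: str = field(init=False)

    def __post_init__(self) -> None:
        if self.days_since_relocation < 0:
            raise ValidationError(
                f"turnover {self.specimen_id}: days_since_relocation must be >= 0"
            )
        if not _finite(self.d2h):
            raise ValidationError(f"turnover {self.specimen_id}: non-finite δ²H")
        if self.tissue not in TISSUES:
            raise ValidationError(
                f"turnover {self.specimen_id}: tissue {self.tissue!r} not in {TISSUES}"
            )
        self.group = turnover_group(self.days_since_relocation)


@dataclass
class TrafficRecord:
    """Annual number of inbound flights from one candidate source region."""

    source_region_id: str
    flights_per_year: float
    latitude: float

    def __post_init__(self) -> None:
        if self.flights_per_year < 0:
            raise ValidationError(
                f"traffic {self.source_region_id}: flights_per_year must be >= 0"
            )


@dataclass
class SurveillanceRecord:
    """One year of trapping / spraying / aircraft-inspection effort."""

    year: int
    beetles_per_aircraft: float | None
    beetles_trapped: float | None = None
    acres_sprayed: float | None = None
    traps_deployed: float | None = None

    def __post_init__(self) -> None:
        for name in ("beetles_per_aircraft", "beetles_trapped", "acres_sprayed",
                     "traps_deployed"):
            v = getattr(self, name)
            if v is not None and v == v and v < 0:
                raise ValidationError(f"surveillance {self.year}: {name} must be >= 0")


def validate_locations(locations: Sequence[LocationRecord]) -> None:
    """Cross-record invariants: ids unique, exactly one monitored-site record."""
    ids = [loc.location_id for loc in locations]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate location_id in locations")
    n_pdx = sum(1 for loc in locations if loc.role == "pdx")
    if n_pdx != 1:
        raise ValidationError(f"expected exactly one location with role 'pdx', got {n_pdx}")
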