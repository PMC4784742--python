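"""Reading, validating and writing the tabular analysis inputs.

The package's native dialect is UTF-8 CSV, one file per input role:

- ``locations.csv``:    location_id, latitude, role, m01..m12, annual_var
- ``specimens.csv``:    specimen_id, cohort, location_id, date, d2h
- ``turnover.csv``:     specimen_id, days, tissue, d2h[, mass_ug]
- ``traffic.csv``:      source_region_id, latitude, flights_per_year
- ``surveillance.csv``: year, beetles_per_aircraft, beetles_trapped,
  acres_sprayed, traps

An optional converter (requires openpyxl via pandas) ingests Excel
workbooks with the same column layout.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml

from .datatypes import (
    LocationRecord,
    SchemaError,
    SpecimenRecord,
    SurveillanceRecord,
    TrafficRecord,
    TurnoverObservation,
    ValidationError,
    validate_locations,
)

logger = logging.getLogger("isosentinel")

MONTH_COLS = [f"m{m:02d}" for m in range(1, 13)]

_SCHEMAS = {
    "locations": ["location_id", "latitude", "role", *MONTH_COLS, "annual_var"],
    "specimens": ["specimen_id", "cohort", "location_id", "date", "d2h"],
    "turnover": ["specimen_id", "days", "tissue", "d2h"],
    "traffic": ["source_region_id", "latitude", "flights_per_year"],
    "surveillance": ["year", "beetles_per_aircraft", "beetles_trapped",
                     "acres_sprayed", "traps"],
}


@dataclass
class AnalysisConfig:
    """Run-level constants and MCMC settings.

    Prior constants default to the published analysis: composite-region
    prior mass 0.20, time-since-arrival truncated to (0.5, 60) days, a
    90-day end-member averaging window, and turnover breakpoints at
    14 and 35 days.
    """

    seed: int = 1234
    n_chains: int = 3
    n_iter: int = 20000
    n_burn: int = 5000
    composite_prior_mass: float = 0.20
    time_bounds: tuple[float, float] = (0.5, 60.0)
    window_days: int = 90
    breakpoints: tuple[float, float] = (14.0, 35.0)
    ramp_convention: str = "shifted"  # or "literal"; see turnover module

    def __post_init__(self) -> None:
        if self.ramp_convention not in ("shifted", "literal"):
            raise ValidationError(f"unknown ramp_convention {self.ramp_convention!r}")
        if self.n_iter <= self.n_burn:
            raise ValidationError("n_iter must exceed n_burn")

    @classmethod
    def from_file(cls, path: str | Path) -> "AnalysisConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise SchemaError(f"unknown config keys: {sorted(unknown)}")
        if "time_bounds" in data:
            data["time_bounds"] = tuple(data["time_bounds"])
        if "breakpoints" in data:
            data["breakpoints"] = tuple(data["breakpoints"])
        return cls(**data)


@dataclass
class InputBundle:
    """All validated inputs for one analysis run."""

    locations: list[LocationRecord]
    specimens: list[SpecimenRecord]
    turnover: list[TurnoverObservation]
    traffic: list[TrafficRecord]
    surveillance: list[SurveillanceRecord]

    @property
    def vouchers(self) -> list[SpecimenRecord]:
        return [s for s in self.specimens if s.cohort == "voucher"]

    @property
    def pdx_specimens(self) -> list[SpecimenRecord]:
        return [s for s in self.specimens if s.cohort == "pdx"]

    @property
    def pdx_location(self) -> LocationRecord:
        return next(loc for loc in self.locations if loc.role == "pdx")


def _read_table(path: str | Path, kind: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix in (".xlsx", ".xls"):
        df = pd.read_excel(path)
    else:
        # round_trip parser: bit-exact read-back of %.17g-formatted floats
        df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in _SCHEMAS[kind] if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing column(s) {missing}")
    return df


def read_locations(path: str | Path) -> list[LocationRecord]:
    df = _read_table(path, "locations")
    records = [
        LocationRecord(
            location_id=str(row.location_id),
            latitude=float(row.latitude),
            role=str(row.role),
            precip_monthly_pred=tuple(float(getattr(row, c)) for c in MONTH_COLS),
            precip_annual_var=float(row.annual_var),
        )
        for row in df.itertuples(index=False)
    ]
    validate_locations(records)
    return records


def read_specimens(path: str | Path) -> list[SpecimenRecord]:
    df = _read_table(path, "specimens")
    records = []
    for row in df.itertuples(index=False):
        d2h = float(row.d2h)
        if not math.isfinite(d2h):
            raise ValidationError(f"specimen {row.specimen_id}: non-finite δ²H")
        records.append(
            SpecimenRecord(
                specimen_id=str(row.specimen_id),
                cohort=str(row.cohort),
                location_id=str(row.location_id),
                collection_date=_dt.date.fromisoformat(str(row.date)),
                d2h=d2h,
            )
        )
    return records


def read_turnover(path: str | Path) -> list[TurnoverObservation]:
    df = _read_table(path, "turnover")
    return [
        TurnoverObservation(
            specimen_id=str(row.specimen_id),
            days_since_relocation=float(row.days),
            tissue=str(row.tissue),
            d2h=float(row.d2h),
        )
        for row in df.itertuples(index=False)
    ]


def read_traffic(path: str | Path) -> list[TrafficRecord]:
    df = _read_table(path, "traffic")
    records = [
        TrafficRecord(
            source_region_id=str(row.source_region_id),
            latitude=float(row.latitude),
            flights_per_year=float(row.flights_per_year),
        )
        for row in df.itertuples(index=False)
    ]
    if records and not any(t.flights_per_year > 0 for t in records):
        raise ValidationError("traffic: at least one region must have flights > 0")
    return records


def read_surveillance(path: str | Path) -> list[SurveillanceRecord]:
    df = _read_table(path, "surveillance")

    def _opt(v) -> float | None:
        v = float(v)
        return None if math.isnan(v) else v

    return [
        SurveillanceRecord(
            year=int(row.year),
            beetles_per_aircraft=_opt(row.beetles_per_aircraft),
            beetles_trapped=_opt(row.beetles_trapped),
            acres_sprayed=_opt(row.acres_sprayed),
            traps_deployed=_opt(row.traps),
        )
        for row in df.itertuples(index=False)
    ]


def read_inputs(paths: dict[str, str | Path] | str | Path,
                config: AnalysisConfig | None = None) -> InputBundle:
    """Read and validate the full input set.

    ``paths`` is either a directory containing the five canonically named
    CSV files, or a mapping from role ('locations', 'specimens', ...) to path.
    """
    if isinstance(paths, (str, Path)):
        base = Path(paths)
        paths = {k: base / f"{k}.csv" for k in _SCHEMAS}
    bundle = InputBundle(
        locations=read_locations(paths["locations"]),
        specimens=read_specimens(paths["specimens"]),
        turnover=read_turnover(paths["turnover"]),
        traffic=read_traffic(paths["traffic"]),
        surveillance=read_surveillance(paths["surveillance"]),
    )
    logger.info(
        "read %d locations (%d sources), %d specimens (%d vouchers, %d pdx), "
        "%d turnover obs, %d traffic regions, %d surveillance years",
        len(bundle.locations),
        sum(1 for l in bundle.locations if l.role == "source"),
        len(bundle.specimens), len(bundle.vouchers), len(bundle.pdx_specimens),
        len(bundle.turnover), len(bundle.traffic), len(bundle.surveillance),
    )
    return bundle


# ---------------------------------------------------------------- writers

def write_locations(locations: Sequence[LocationRecord], path: str | Path) -> None:
    rows = []
    for loc in locations:
        row = {"location_id": loc.location_id, "latitude": loc.latitude,
               "role": loc.role}
        row.update({c: v for c, v in zip(MONTH_COLS, loc.precip_monthly_pred)})
        row["annual_var"] = loc.precip_annual_var
        rows.append(row)
    pd.DataFrame(rows, columns=_SCHEMAS["locations"]).to_csv(path, index=False, float_format="%.17g")


def write_specimens(specimens: Sequence[SpecimenRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {"specimen_id": s.specimen_id, "cohort": s.cohort,
             "location_id": s.location_id,
             "date": s.collection_date.isoformat(), "d2h": s.d2h}
            for s in specimens
        ],
        columns=_SCHEMAS["specimens"],
    ).to_csv(path, index=False, float_format="%.17g")


def write_turnover(obs: Sequence[TurnoverObservation], path: str | Path) -> None:
    pd.DataFrame(
        [
            {"specimen_id": o.specimen_id, "days": o.days_since_relocation,
             "tissue": o.tissue, "d2h": o.d2h}
            for o in obs
        ],
        columns=_SCHEMAS["turnover"],
    ).to_csv(path, index=False, float_format="%.17g")


def write_traffic(traffic: Sequence[TrafficRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {"source_region_id": t.source_region_id, "latitude": t.latitude,
             "flights_per_year": t.flights_per_year}
            for t in traffic
        ],
        columns=_SCHEMAS["traffic"],
    ).to_csv(path, index=False, float_format="%.17g")


def write_surveillance(records: Sequence[SurveillanceRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {"year": r.year, "beetles_per_aircraft": r.beetles_per_aircraft,
             "beetles_trapped": r.beetles_trapped, "acres_sprayed": r.acres_sprayed,
             "traps": r.traps_deployed}
            for r in records
        ],
        columns=_SCHEMAS["surveillance"],
    ).to_csv(path, index=False, float_format="%.17g")


def write_inputs(bundle: InputBundle, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_locations(bundle.locations, directory / "locations.csv")
    write_specimens(bundle.specimens, directory / "specimens.csv")
    write_turnover(bundle.turnover, directory / "turnover.csv")
    write_traffic(bundle.traffic, directory / "traffic.csv")
    write_surveillance(bundle.surveillance, directory / "surveillance.csv")


# ------------------------------------------------------------ mass balance

def mass_balance_whole(parts: Iterable[tuple[float, float]]) -> float:
    """Whole-organism δ²H reconstructed from part masses and part δ²H.

    ``parts`` is a sequence of (mass_µg, δ²H) pairs; the whole value is the
    mass-weighted mean Σ(mᵢδᵢ)/Σmᵢ. Used to recombine separately analysed
    wings, elytra and body fractions into a single whole-beetle value.
    """
    parts = list(parts)
    if not parts:
        raise ValidationError("mass_balance_whole requires at least one part")
    masses = [float(m) for m, _ in parts]
    if any(m <= 0 for m in masses):
        raise ValidationError("part masses must be > 0")
    total = sum(masses)
    return sum(float(m) * float(d) for m, d in parts) / total
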