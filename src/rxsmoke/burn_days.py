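"""Prescribed-burn day selection from daily meteorology.

Burn bosses screen candidate days against prescription windows from
burning-management guidelines.  The default thresholds implemented here
are: 24-h rain < 6.35 mm/day, relative humidity > 30%, temperature
< 29.4 degC, planetary boundary layer height within [503, 1981] m, surface
wind speed within [3.6, 6.3] m/s, and transport wind speed within
[4.0, 8.9] m/s.  Rain/RH/temperature are strict inequalities (the
guideline states them with < and >); the three "between" quantities are
closed intervals.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, fields

import pandas as pd

__all__ = [
    "MetDay",
    "BurnCriteria",
    "BurnDaySelection",
    "is_burn_day",
    "select_burn_days",
    "read_met_csv",
    "write_met_csv",
]

MET_COLUMNS = ["date", "rain24_mm", "rh_pct", "temp_c", "pbl_m", "wind_ms", "transport_wind_ms"]


@dataclass(frozen=True)
class MetDay:
    """One day of the meteorological quantities screened for burning."""

    date: dt.date
    rain24_mm: float
    rh_pct: float
    temp_c: float
    pbl_m: float
    wind_ms: float
    transport_wind_ms: float

    def validate(self) -> None:
        for f in fields(self):
            if f.name == "date":
                continue
            v = getattr(self, f.name)
            if v is None or not math.isfinite(v):
                raise ValueError(f"MetDay field {f.name!r} is missing or non-finite on {self.date}")
        if not 0.0 <= self.rh_pct <= 100.0:
            raise ValueError(f"rh_pct must be within [0, 100], got {self.rh_pct}")
        if self.rain24_mm < 0:
            raise ValueError("rain24_mm must be nonnegative")
        if self.pbl_m <= 0:
            raise ValueError("pbl_m must be positive")


@dataclass(frozen=True)
class BurnCriteria:
    """Prescription thresholds; see the module docstring for the defaults."""

    rain24_max_mm: float = 6.35
    rh_min_pct: float = 30.0
    temp_max_c: float = 29.4
    pbl_min_m: float = 503.0
    pbl_max_m: float = 1981.0
    wind_min_ms: float = 3.6
    wind_max_ms: float = 6.3
    twind_min_ms: float = 4.0
    twind_max_ms: float = 8.9

    def __post_init__(self) -> None:
        for lo, hi in (
            (self.pbl_min_m, self.pbl_max_m),
            (self.wind_min_ms, self.wind_max_ms),
            (self.twind_min_ms, self.twind_max_ms),
        ):
            if not lo < hi:
                raise ValueError(f"criteria interval [{lo}, {hi}] is empty")
        for f in fields(self):
            if not math.isfinite(getattr(self, f.name)):
                raise ValueError(f"criteria field {f.name} must be finite")


DEFAULT_CRITERIA = BurnCriteria()


def is_burn_day(
    day: MetDay, criteria: BurnCriteria = DEFAULT_CRITERIA
) -> tuple[bool, dict[str, bool]]:
    """Screen one day against the prescription.

    Returns ``(eligible, report)`` where ``report`` maps each criterion
    name to its individual pass/fail.  Pure function of its inputs.
    """
    day.validate()
    report = {
        "rain24": day.rain24_mm < criteria.rain24_max_mm,
        "rh": day.rh_pct > criteria.rh_min_pct,
        "temp": day.temp_c < criteria.temp_max_c,
        "pbl": criteria.pbl_min_m <= day.pbl_m <= criteria.pbl_max_m,
        "wind": criteria.wind_min_ms <= day.wind_ms <= criteria.wind_max_ms,
        "transport_wind": criteria.twind_min_ms <= day.transport_wind_ms <= criteria.twind_max_ms,
    }
    return all(report.values()), report


@dataclass(frozen=True)
class BurnDaySelection:
    """Chosen burn dates plus a flag when fewer than requested exist."""

    dates: tuple[dt.date, ...]
    insufficient: bool

    def __len__(self) -> int:
        return len(self.dates)


def select_burn_days(
    series: list[MetDay],
    n_required: int,
    deadline: dt.date | None = None,
    criteria: BurnCriteria = DEFAULT_CRITERIA,
) -> BurnDaySelection:
    """Pick the earliest ``n_required`` eligible dates on or before ``deadline``.

    Earliest-first maximizes the regrowth-free interval between the last
    treatment and a subsequent wildfire and is deterministic.  If fewer
    eligible days exist the selection is returned short with
    ``insufficient=True``.
    """
    if n_required < 1:
        raise ValueError("n_required must be at least 1")
    dates = [d.date for d in series]
    if any(b <= a for a, b in zip(dates, dates[1:])):
        raise ValueError("met series must be strictly increasing in date")
    chosen: list[dt.date] = []
    for day in series:
        if deadline is not None and day.date > deadline:
            break
        if is_burn_day(day, criteria)[0]:
            chosen.append(day.date)
            if len(chosen) == n_required:
                break
    return BurnDaySelection(tuple(chosen), insufficient=len(chosen) < n_required)


def write_met_csv(series: list[MetDay], path) -> None:
    pd.DataFrame(
        [
            {
                "date": d.date.isoformat(),
                "rain24_mm": d.rain24_mm,
                "rh_pct": d.rh_pct,
                "temp_c": d.temp_c,
                "pbl_m": d.pbl_m,
                "wind_ms": d.wind_ms,
                "transport_wind_ms": d.transport_wind_ms,
            }
            for d in series
        ]
    ).to_csv(path, index=False)


def read_met_csv(path) -> list[MetDay]:
    frame = pd.read_csv(path)
    missing = set(MET_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"met CSV missing columns: {sorted(missing)}")
    return [
        MetDay(
            date=dt.date.fromisoformat(str(row["date"])[:10]),
            rain24_mm=float(row["rain24_mm"]),
            rh_pct=float(row["rh_pct"]),
            temp_c=float(row["temp_c"]),
            pbl_m=float(row["pbl_m"]),
            wind_ms=float(row["wind_ms"]),
            transport_wind_ms=float(row["transport_wind_ms"]),
        )
        for _, row in frame.iterrows()
    ]
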