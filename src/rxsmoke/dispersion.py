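"""Gaussian-puff transport surrogate and pollutant aggregation operators.

Each emitted hour of mass becomes a puff that is advected by the hourly
wind, spreads horizontally with age, and is mixed uniformly from the
ground to max(PBL height, plume top).  A puff whose plume bottom sits
above the boundary layer rides aloft and contributes nothing at ground
level until the growing boundary layer entrains it (binary entrainment;
once entrained, a puff stays mixed to the ground).  Fields superpose
linearly over puffs and species, so the model is a linear tracer: the
secondary chemistry of real smoke (ozone formation in NOx-rich downwind
air, PM2.5 aging) is deliberately out of scope, and gas-like species are
transported exactly like PM.

Horizontal spreading uses cell-integrated Gaussian weights (differences
of error functions per axis), which makes the discrete field conserve
mass exactly on an unbounded grid.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import erf

from .fuels import EmissionSeries
from .grid import GridGeometry

__all__ = [
    "DispersionParams",
    "HourlyField",
    "ImpactField",
    "simulate",
    "daily_average",
    "mda8",
    "max_1h",
    "smoke_impact",
]

TONS_TO_UG = 1e12


@dataclass(frozen=True)
class DispersionParams:
    """Puff-growth and lifetime settings.

    sigma (in cells) grows linearly with puff age: sigma0_cells +
    growth_cells_per_h * age.  Puffs are dropped after ``max_age_h``
    (48 h by default — regional smoke transport rarely matters longer).
    ``decay_per_h`` is an optional first-order loss rate.
    ``min_mixing_m`` guards against division by a vanishing mixing depth.

    ``entrainment`` selects how an elevated plume reaches the ground:
    "binary" (default) gives zero ground contribution while the plume
    bottom rides above the boundary layer and full mixing once the PBL
    first overtakes it; "proportional" grounds, each hour, the fraction
    of the uniform bottom-to-top plume slab that lies below the PBL.
    """

    sigma0_cells: float = 0.5
    growth_cells_per_h: float = 0.3
    max_age_h: int = 48
    decay_per_h: float = 0.0
    min_mixing_m: float = 50.0
    entrainment: str = "binary"

    def __post_init__(self) -> None:
        if self.entrainment not in ("binary", "proportional"):
            raise ValueError("entrainment must be 'binary' or 'proportional'")


@dataclass
class HourlyField:
    """Hourly gridded concentrations per species (ug/m3 equivalents)."""

    times: pd.DatetimeIndex
    data: dict  # species -> (n_hours, n_rows, n_cols)
    geometry: GridGeometry

    def __add__(self, other: "HourlyField") -> "HourlyField":
        if not self.times.equals(other.times) or not self.geometry.matches(other.geometry):
            raise ValueError("fields must share hours and geometry to superpose")
        data = {
            sp: self.data.get(sp, 0) + other.data.get(sp, 0)
            for sp in set(self.data) | set(other.data)
        }
        return HourlyField(self.times, data, self.geometry)


@dataclass
class ImpactField:
    """Daily pollutant metric on the grid: (day, row, col)."""

    pollutant: str
    days: list  # list of dt.date
    values: np.ndarray  # (n_days, n_rows, n_cols)
    geometry: GridGeometry
    scenario: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("impact values must be (day, row, col)")
        if self.values.shape[0] != len(self.days):
            raise ValueError("one layer per day required")
        if self.values.shape[1:] != self.geometry.shape:
            raise ValueError("impact grid shape mismatch")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("impact field must be finite")


def _cell_weights(centers: np.ndarray, mu: float, sigma: float, cell: float) -> np.ndarray:
    """Exact integral of a 1D Gaussian over each cell interval."""
    scale = 1.0 / (sigma * np.sqrt(2.0))
    hi = erf((centers + cell / 2 - mu) * scale)
    lo = erf((centers - cell / 2 - mu) * scale)
    return 0.5 * np.abs(hi - lo)


def _wind_arrays(winds: pd.DataFrame, times: pd.DatetimeIndex):
    w = winds.set_index("timestamp") if "timestamp" in winds.columns else winds
    w.index = pd.DatetimeIndex(w.index)
    missing = times.difference(w.index)
    if len(missing):
        raise ValueError(
            f"winds do not cover the emission window plus max age: missing {missing[0]}"
        )
    w = w.loc[times]
    return w["u_ms"].to_numpy(), w["v_ms"].to_numpy(), w["pbl_m"].to_numpy()


def simulate(
    emissions: EmissionSeries,
    source_cell: tuple[int, int],
    winds: pd.DataFrame,
    geometry: GridGeometry,
    params: DispersionParams = DispersionParams(),
) -> HourlyField:
    """Transport an emission series from one source cell.

    ``winds`` must carry hourly ``timestamp``, ``u_ms``, ``v_ms`` and
    ``pbl_m`` covering the emission window plus ``params.max_age_h``.
    Returns ground-level concentrations in ug/m3 per species (tons in,
    micrograms over mixed volume out).
    """
    n_em = len(emissions.times)
    times = pd.date_range(emissions.times[0], periods=n_em + params.max_age_h, freq="h")
    u, v, pbl = _wind_arrays(winds, times)
    if np.any(pbl <= 0):
        raise ValueError("PBL height must be positive")

    xc = geometry.x_centers()
    yc = geometry.y_centers()
    cell = geometry.cell_size_m
    cell_area = geometry.cell_area_m2
    sx, sy = geometry.cell_center(*source_cell)

    out = {sp: np.zeros((len(times), geometry.n_rows, geometry.n_cols)) for sp in emissions.species}
    species_mass = {sp: arr * TONS_TO_UG for sp, arr in emissions.species.items()}

    for k0 in range(n_em):
        masses = {sp: species_mass[sp][k0] for sp in species_mass}
        if all(m == 0.0 for m in masses.values()):
            continue
        bottom = float(emissions.plume_bottom_m[k0])
        top = float(emissions.plume_top_m[k0])
        x, y = sx, sy
        entrained = False
        for age in range(params.max_age_h + 1):
            ti = k0 + age
            if ti >= len(times):
                break
            if params.entrainment == "binary":
                if not entrained and bottom < pbl[ti]:
                    entrained = True
                ground_frac = 1.0 if entrained else 0.0
            else:  # proportional slab overlap with the boundary layer
                depth = top - bottom
                if depth <= 0:
                    ground_frac = 1.0 if bottom < pbl[ti] else 0.0
                else:
                    ground_frac = np.clip((pbl[ti] - bottom) / depth, 0.0, 1.0)
            if ground_frac > 0:
                h_mix = max(pbl[ti], top, params.min_mixing_m)
                sigma = (params.sigma0_cells + params.growth_cells_per_h * age) * cell
                wx = _cell_weights(xc, x, sigma, cell)
                wy = _cell_weights(yc, y, sigma, cell)
                kernel = np.outer(wy, wx) * (ground_frac / (cell_area * h_mix))
                decay = np.exp(-params.decay_per_h * age)
                for sp, m in masses.items():
                    if m:
                        out[sp][ti] += m * decay * kernel
            # advect to the next hour's position
            x += u[ti] * 3600.0
            y += v[ti] * 3600.0
    return HourlyField(times, out, geometry)


def _split_days(times: pd.DatetimeIndex):
    days = pd.DatetimeIndex(times.normalize())
    unique = days.unique()
    return [(d.date(), np.flatnonzero(days == d)) for d in unique]


def daily_average(field: HourlyField, species: str, scenario: str = "") -> ImpactField:
    """Per-cell mean of each calendar day's hourly values."""
    arr = field.data[species]
    days, layers = [], []
    for day, idx in _split_days(field.times):
        days.append(day)
        layers.append(arr[idx].mean(axis=0))
    return ImpactField(species, days, np.stack(layers), field.geometry, scenario)


def mda8(field: HourlyField, species: str, scenario: str = "") -> ImpactField:
    """Daily maximum 8-h rolling mean (windows starting 00:00-16:00).

    Windows never cross midnight; a day shorter than 8 hours falls back
    to its plain mean.
    """
    arr = field.data[species]
    days, layers = [], []
    for day, idx in _split_days(field.times):
        sub = arr[idx]
        n = sub.shape[0]
        if n < 8:
            layers.append(sub.mean(axis=0))
        else:
            csum = np.concatenate([np.zeros((1,) + sub.shape[1:]), np.cumsum(sub, axis=0)])
            windows = (csum[8:] - csum[:-8]) / 8.0  # one per start hour 0..n-8
            layers.append(windows.max(axis=0))
        days.append(day)
    return ImpactField(species, days, np.stack(layers), field.geometry, scenario)


def max_1h(field: HourlyField, species: str, scenario: str = "") -> ImpactField:
    """Per-cell daily maximum of hourly values."""
    arr = field.data[species]
    days, layers = [], []
    for day, idx in _split_days(field.times):
        days.append(day)
        layers.append(arr[idx].max(axis=0))
    return ImpactField(species, days, np.stack(layers), field.geometry, scenario)


def smoke_impact(scenario_field: ImpactField, baseline: ImpactField) -> ImpactField:
    """Scenario minus baseline, preserving negative differences."""
    if scenario_field.values.shape != baseline.values.shape:
        raise ValueError("scenario and baseline fields must share shape")
    if not scenario_field.geometry.matches(baseline.geometry):
        raise ValueError("scenario and baseline fields must share geometry")
    return ImpactField(
        scenario_field.pollutant,
        scenario_field.days,
        scenario_field.values - baseline.values,
        scenario_field.geometry,
        scenario_field.scenario,
    )
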