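"""Seeded synthetic inputs with the statistical structure the analysis assumes.

Every generator here stands in for a real-data source: the land-cover /
slope pair emulates 30-m NLCD and LANDFIRE rasters (burnable forest cut
by connected firebreak corridors of water, developed land and barren
ground); the daily met series emulates a multi-month model extraction in
which a tunable fraction of days satisfies the burn prescription; the
population surface is a clustered settlement pattern (one near-fire town
plus distant cities); hourly winds drive the dispersion surrogate.

All generators are bit-reproducible: one global seed fans out to
per-generator streams through a fixed stream-index table, so adding a
generator never perturbs the others.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .burn_days import DEFAULT_CRITERIA, BurnCriteria, MetDay, is_burn_day
from .dispersion import ImpactField
from .grid import GridGeometry, RasterGrid

__all__ = [
    "LandscapeParams",
    "WATER",
    "DEVELOPED",
    "BARREN",
    "FOREST_DECIDUOUS",
    "FOREST_EVERGREEN",
    "FIREBREAK_CLASSES",
    "make_landscape",
    "make_met_series",
    "make_population",
    "make_winds",
    "make_monitor_obs",
]

# Internal land-cover class table (codes are package-local, not NLCD's).
WATER = 11
DEVELOPED = 21
BARREN = 31
FOREST_DECIDUOUS = 41
FOREST_EVERGREEN = 42
FIREBREAK_CLASSES = frozenset({WATER, DEVELOPED, BARREN})

# stream indices for the seed fan-out (never renumber, only append)
_STREAM_LANDSCAPE = 0
_STREAM_MET = 1
_STREAM_POPULATION = 2
_STREAM_WINDS = 3
_STREAM_MONITORS = 4


def _rng(seed: int, stream: int, attempt: int = 0) -> np.random.Generator:
    return np.random.default_rng([int(seed), stream, attempt])


@dataclass(frozen=True)
class LandscapeParams:
    """Firebreak corridor fractions and terrain texture.

    Fractions are approximate areal shares of each firebreak class; a
    zero fraction omits that class entirely.  ``patch_sigma`` sets the
    correlation length (in cells) of the forest mosaic and the synthetic
    elevation surface; ``relief_m`` scales terrain so slopes span gentle
    and steep (up to roughly 50 degrees at the default cell size).
    """

    water_frac: float = 0.05
    developed_frac: float = 0.04
    barren_frac: float = 0.03
    patch_sigma: float = 5.0
    relief_m: float = 900.0

    def __post_init__(self) -> None:
        for name in ("water_frac", "developed_frac", "barren_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


def _corridor(shape, rng, vertical: bool, frac: float) -> np.ndarray:
    """A connected random-walk corridor spanning the grid, width from frac."""
    n_rows, n_cols = shape
    mask = np.zeros(shape, dtype=bool)
    if frac <= 0:
        return mask
    if vertical:
        length, breadth = n_rows, n_cols
    else:
        length, breadth = n_cols, n_rows
    width = max(1, round(frac * n_rows * n_cols / length))
    pos = int(rng.integers(breadth // 4, 3 * breadth // 4))
    for i in range(length):
        pos = int(np.clip(pos + rng.integers(-1, 2), 0, breadth - 1))
        lo = max(0, pos - width // 2)
        hi = min(breadth, lo + width)
        if vertical:
            mask[i, lo:hi] = True
        else:
            mask[lo:hi, i] = True
    return mask


def _smooth_noise(rng, shape, sigma) -> np.ndarray:
    return ndimage.gaussian_filter(rng.standard_normal(shape), sigma, mode="reflect")


def make_landscape(
    n_rows: int,
    n_cols: int,
    cell_size_m: float,
    seed: int,
    params: LandscapeParams = LandscapeParams(),
) -> tuple[RasterGrid, RasterGrid]:
    """Generate a (landcover, slope) raster pair.

    Land cover holds two burnable forest classes (a smoothed-noise
    mosaic) cut by connected corridors: a meandering river (water), a
    road (developed) and a barren strip.  Slope is the gradient magnitude
    of a smoothed synthetic elevation surface, in degrees within [0, 60].
    The result always contains at least one burnable 8-connected
    component of >= 100 cells (regenerated with an internal sub-seed a
    bounded number of times if necessary).
    """
    if n_rows < 16 or n_cols < 16:
        raise ValueError("landscape must be at least 16 x 16 cells")
    shape = (n_rows, n_cols)
    for attempt in range(10):
        rng = _rng(seed, _STREAM_LANDSCAPE, attempt)
        forest_noise = _smooth_noise(rng, shape, params.patch_sigma)
        landcover = np.where(forest_noise > 0, FOREST_DECIDUOUS, FOREST_EVERGREEN)
        # corridors drawn water -> barren -> developed; later classes overwrite
        landcover[_corridor(shape, rng, True, params.water_frac)] = WATER
        landcover[_corridor(shape, rng, True, params.barren_frac)] = BARREN
        landcover[_corridor(shape, rng, False, params.developed_frac)] = DEVELOPED

        elev = _smooth_noise(rng, shape, params.patch_sigma)
        span = elev.max() - elev.min()
        elev = (elev - elev.min()) / (span if span > 0 else 1.0) * params.relief_m
        gy, gx = np.gradient(elev, cell_size_m)
        slope = np.degrees(np.arctan(np.hypot(gx, gy)))
        slope = np.clip(slope, 0.0, 60.0)

        ok_classes = all(
            frac <= 0 or (landcover == code).any()
            for frac, code in (
                (params.water_frac, WATER),
                (params.barren_frac, BARREN),
                (params.developed_frac, DEVELOPED),
            )
        )
        burnable = ~np.isin(landcover, sorted(FIREBREAK_CLASSES))
        labels, n = ndimage.label(burnable, structure=np.ones((3, 3), bool))
        big_enough = n > 0 and np.bincount(labels.ravel())[1:].max() >= 100
        if ok_classes and big_enough and (landcover == FOREST_DECIDUOUS).any() and (
            landcover == FOREST_EVERGREEN
        ).any():
            return (
                RasterGrid(landcover.astype(np.int16), cell_size_m),
                RasterGrid(slope, cell_size_m),
            )
    raise RuntimeError("could not generate a landscape satisfying the invariants")


def make_met_series(
    start_date: dt.date,
    n_days: int,
    seed: int,
    favorable_target: float = 0.2,
    criteria: BurnCriteria = DEFAULT_CRITERIA,
) -> list[MetDay]:
    """Daily met series with a tunable share of prescription-eligible days.

    Each day is favorable with probability ``favorable_target``;
    favorable days are drawn uniformly inside every criterion window,
    unfavorable days from wide climatological ranges with at least one
    forced violation (low RH), so the realized eligible fraction
    concentrates tightly around the target.
    """
    if n_days < 1:
        raise ValueError("n_days must be at least 1")
    if not 0.0 <= favorable_target <= 1.0:
        raise ValueError("favorable_target must be in [0, 1]")
    rng = _rng(seed, _STREAM_MET)
    c = criteria
    out: list[MetDay] = []
    for i in range(n_days):
        date = start_date + dt.timedelta(days=i)
        favorable = rng.random() < favorable_target
        if favorable:
            day = MetDay(
                date=date,
                rain24_mm=float(rng.uniform(0.0, c.rain24_max_mm * 0.9)),
                rh_pct=float(rng.uniform(c.rh_min_pct + 5, 90.0)),
                temp_c=float(rng.uniform(2.0, c.temp_max_c - 4)),
                pbl_m=float(rng.uniform(c.pbl_min_m + 50, c.pbl_max_m - 80)),
                wind_ms=float(rng.uniform(c.wind_min_ms + 0.1, c.wind_max_ms - 0.1)),
                transport_wind_ms=float(rng.uniform(c.twind_min_ms + 0.1, c.twind_max_ms - 0.1)),
            )
        else:
            day = MetDay(
                date=date,
                rain24_mm=float(rng.exponential(4.0)),
                rh_pct=float(rng.uniform(5.0, c.rh_min_pct - 5)),  # forced violation
                temp_c=float(rng.uniform(-5.0, 35.0)),
                pbl_m=float(rng.uniform(200.0, 2500.0)),
                wind_ms=float(rng.uniform(0.5, 12.0)),
                transport_wind_ms=float(rng.uniform(1.0, 14.0)),
            )
        out.append(day)
    return out


def make_population(
    geometry: GridGeometry | RasterGrid,
    seed: int,
    n_centers: int = 3,
    total_pop: float = 1e6,
    centers: list | None = None,
) -> RasterGrid:
    """Clustered population surface summing exactly to ``total_pop``.

    Gaussian settlement blobs over a thin rural floor; ``n_centers=0``
    yields a uniform surface.  ``centers`` optionally pins blob locations
    as (row, col) pairs (``None`` entries are placed randomly) — used to
    put one town near the fire and the other cities at distance.
    """
    if total_pop < 0:
        raise ValueError("total_pop must be nonnegative")
    if n_centers < 0:
        raise ValueError("n_centers must be nonnegative")
    geom = geometry.geometry if isinstance(geometry, RasterGrid) else geometry
    if centers is not None and len(centers) != n_centers:
        raise ValueError("centers, when given, must have one entry per center")
    rng = _rng(seed, _STREAM_POPULATION)
    rr, cc = np.meshgrid(np.arange(geom.n_rows), np.arange(geom.n_cols), indexing="ij")
    field = np.ones(geom.shape) * 0.02
    scale = max(geom.n_rows, geom.n_cols) / 12.0
    for k in range(n_centers):
        pinned = centers[k] if centers is not None else None
        if pinned is not None:
            r0, c0 = float(pinned[0]), float(pinned[1])
            rng.uniform(0, geom.n_rows), rng.uniform(0, geom.n_cols)  # keep stream aligned
        else:
            r0 = rng.uniform(0, geom.n_rows)
            c0 = rng.uniform(0, geom.n_cols)
        amp = rng.uniform(0.5, 2.0)
        field += amp * np.exp(-((rr - r0) ** 2 + (cc - c0) ** 2) / (2 * scale**2))
    if n_centers == 0:
        field = np.ones(geom.shape)
    field = field / field.sum() * total_pop
    return RasterGrid.from_geometry(geom, field)


def make_winds(
    start: dt.datetime,
    n_hours: int,
    seed: int,
    mean_u_ms: float = 2.5,
    mean_v_ms: float = 0.5,
    storm_start: dt.datetime | None = None,
    storm_hours: int = 0,
    storm_factor: float = 1.0,
) -> pd.DataFrame:
    """Hourly transport winds and PBL heights (AR(1)-smooth components).

    PBL follows a diurnal cycle from ~250 m at night to ~1600 m mid
    afternoon with mild day-to-day variability; all heights positive.
    An optional storm window multiplies the wind components by
    ``storm_factor`` — emulating a wind-driven fire event, where strong
    transport winds both carry smoke far and flatten plume rise.
    """
    if n_hours < 1:
        raise ValueError("n_hours must be at least 1")
    rng = _rng(seed, _STREAM_WINDS)
    phi = 0.92
    noise_sd = 0.8

    def ar1(mean):
        x = np.empty(n_hours)
        x[0] = mean + rng.normal(0, noise_sd)
        for i in range(1, n_hours):
            x[i] = mean + phi * (x[i - 1] - mean) + rng.normal(0, noise_sd * np.sqrt(1 - phi**2))
        return x

    times = pd.date_range(pd.Timestamp(start), periods=n_hours, freq="h")
    hour = times.hour.to_numpy()
    diurnal = 250.0 + 1350.0 * np.exp(-((hour - 14.0) ** 2) / (2 * 3.5**2))
    pbl = diurnal * np.exp(rng.normal(0, 0.1, n_hours))
    u, v = ar1(mean_u_ms), ar1(mean_v_ms)
    if storm_start is not None and storm_hours > 0:
        t0 = pd.Timestamp(storm_start)
        in_storm = (times >= t0) & (times < t0 + pd.Timedelta(hours=storm_hours))
        u = np.where(in_storm, u * storm_factor, u)
        v = np.where(in_storm, v * storm_factor, v)
    return pd.DataFrame({"timestamp": times, "u_ms": u, "v_ms": v, "pbl_m": pbl})


def make_monitor_obs(
    truth: ImpactField, n_monitors: int, noise_sd: float, seed: int
) -> pd.DataFrame:
    """Paired model/observation table: truth at monitor cells + Gaussian noise.

    Fixture for evaluation-statistic tests.  Columns: site, date, model, obs.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    n_cells = truth.geometry.n_rows * truth.geometry.n_cols
    if n_monitors > n_cells:
        raise ValueError(f"cannot place {n_monitors} monitors on {n_cells} cells")
    if n_monitors < 1:
        raise ValueError("n_monitors must be at least 1")
    rng = _rng(seed, _STREAM_MONITORS)
    flat = rng.choice(n_cells, size=n_monitors, replace=False)
    rows_idx, cols_idx = np.unravel_index(flat, truth.geometry.shape)
    records = []
    for site, (r, c) in enumerate(zip(rows_idx, cols_idx)):
        for d, day in enumerate(truth.days):
            model = float(truth.values[d, r, c])
            records.append(
                {
                    "site": site,
                    "date": day,
                    "model": model,
                    "obs": model + float(rng.normal(0, noise_sd)) if noise_sd > 0 else model,
                }
            )
    return pd.DataFrame(records)
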