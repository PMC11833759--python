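"""Population-level exposure statistics.

The two headline statistics are the population-weighted concentration

    PWC_t = sum_ij c_ijt * pop_ij / sum_ij pop_ij        (over a region)

and person-days, the population count in cells whose impact
concentration exceeds a threshold, accumulated over cells and days:

    PD = sum_t sum_ij H(c_ijt - threshold) * pop_ij

with H the unit step.  "Exceeds" is read strictly (H(0) = 0); an
inclusive mode is available because step-function conventions differ
between analyses.  The prescribed-fire benefit is

    PD_Rx_benefit = PD_WF - PD_Rx - PD_postRxWF,

positive when treatment prevented exposure.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dispersion import ImpactField
from .grid import GridGeometry, RasterGrid

logger = logging.getLogger(__name__)

__all__ = [
    "RegionMask",
    "regrid_population",
    "population_weighted_concentration",
    "person_days",
    "pd_benefit",
    "person_days_curve",
    "analysis_window",
]


@dataclass(frozen=True)
class RegionMask:
    """Named binary mask on the concentration grid (a county/state analog)."""

    name: str
    mask: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "mask", np.asarray(self.mask, dtype=bool))


def _nearest_index(fine_centers: np.ndarray, coarse_centers: np.ndarray) -> np.ndarray:
    """Index of the nearest coarse center for each fine center (1D)."""
    order = np.argsort(coarse_centers)
    sorted_c = coarse_centers[order]
    pos = np.searchsorted(sorted_c, fine_centers)
    pos = np.clip(pos, 1, len(sorted_c) - 1)
    left = sorted_c[pos - 1]
    right = sorted_c[pos]
    nearest_sorted = np.where(np.abs(fine_centers - left) <= np.abs(right - fine_centers), pos - 1, pos)
    return order[nearest_sorted]


def regrid_population(fine: RasterGrid, coarse: GridGeometry) -> RasterGrid:
    """Aggregate a fine population raster onto a coarser grid.

    Each fine cell's population is assigned whole to the coarse cell
    whose center is nearest to the fine cell's center, so the total is
    conserved exactly — sampling the coarse grid would not be, and
    person-day counts require true population totals.
    """
    if fine.cell_size_m > coarse.cell_size_m * (1 + 1e-9):
        raise ValueError("fine grid must not be coarser than the target grid")
    if np.any(fine.values < 0):
        raise ValueError("population must be nonnegative")
    fx, fy = fine.geometry.x_centers(), fine.geometry.y_centers()
    cx, cy = coarse.x_centers(), coarse.y_centers()
    if fx.max() < cx.min() - coarse.cell_size_m or fx.min() > cx.max() + coarse.cell_size_m:
        raise ValueError("fine and coarse grid extents are disjoint")
    if fy.max() < cy.min() - coarse.cell_size_m or fy.min() > cy.max() + coarse.cell_size_m:
        raise ValueError("fine and coarse grid extents are disjoint")
    col_idx = _nearest_index(fx, cx)
    row_idx = _nearest_index(fy, cy)
    out = np.zeros(coarse.shape)
    rows = np.repeat(row_idx, fine.n_cols)
    cols = np.tile(col_idx, fine.n_rows)
    np.add.at(out, (rows, cols), fine.values.ravel())
    return RasterGrid.from_geometry(coarse, out)


def _check_alignment(impact: ImpactField, pop: RasterGrid) -> None:
    if not impact.geometry.matches(pop.geometry):
        raise ValueError("population must live on the concentration grid geometry")


def population_weighted_concentration(
    impact: ImpactField,
    pop: RasterGrid,
    region: RegionMask | None = None,
    day: int | dt.date | None = None,
) -> float | np.ndarray:
    """Population-weighted mean concentration over a region.

    ``day`` may be an index, a date, or None for the vector of all days.
    Raises on zero regional population rather than silently returning 0.
    """
    _check_alignment(impact, pop)
    mask = region.mask if region is not None else np.ones(pop.values.shape, dtype=bool)
    if mask.shape != pop.values.shape:
        raise ValueError("region mask must share the grid shape")
    weights = np.where(mask, pop.values, 0.0)
    total = weights.sum()
    if total <= 0:
        name = region.name if region is not None else "domain"
        raise ValueError(f"population-weighted concentration undefined: zero population in {name}")
    pwc_all = np.tensordot(impact.values, weights, axes=([1, 2], [0, 1])) / total
    if day is None:
        return pwc_all
    if isinstance(day, dt.date) and not isinstance(day, dt.datetime):
        day = impact.days.index(day)
    return float(pwc_all[day])


def person_days(
    impact: ImpactField,
    pop: RasterGrid,
    threshold: float,
    region: RegionMask | None = None,
    inclusive: bool = False,
) -> float:
    """Person-days of exposure above a concentration threshold."""
    if threshold < 0:
        raise ValueError("threshold must be nonnegative")
    _check_alignment(impact, pop)
    exceed = impact.values >= threshold if inclusive else impact.values > threshold
    weights = pop.values
    if region is not None:
        weights = np.where(region.mask, weights, 0.0)
    return float((exceed * weights).sum())


def pd_benefit(pd_wf: float, pd_rx: float, pd_postrx: float) -> float:
    """Person-days prevented by treatment; positive means exposure avoided."""
    for name, v in (("pd_wf", pd_wf), ("pd_rx", pd_rx), ("pd_postrx", pd_postrx)):
        if v < 0:
            raise ValueError(f"{name} must be nonnegative, got {v}")
    return pd_wf - pd_rx - pd_postrx


def person_days_curve(
    fields: dict,
    pop: RasterGrid,
    thresholds: list[float],
    region: RegionMask | None = None,
    inclusive: bool = False,
) -> pd.DataFrame:
    """PD per scenario per threshold plus the benefit line.

    ``fields`` maps the case labels 'WF', 'Rx' and 'postRxWF' to impact
    fields (a missing case counts zero person-days).  Columns:
    threshold, pd_wf, pd_rx, pd_postrx, pd_scenario3, pd_rx_benefit.
    """
    thresholds = list(thresholds)
    if thresholds != sorted(thresholds):
        logger.info("thresholds were unsorted; sorting ascending")
        thresholds = sorted(thresholds)
    rows = []
    for thr in thresholds:
        vals = {}
        for case in ("WF", "Rx", "postRxWF"):
            f = fields.get(case)
            vals[case] = person_days(f, pop, thr, region, inclusive) if f is not None else 0.0
        rows.append(
            {
                "threshold": thr,
                "pd_wf": vals["WF"],
                "pd_rx": vals["Rx"],
                "pd_postrx": vals["postRxWF"],
                "pd_scenario3": vals["Rx"] + vals["postRxWF"],
                "pd_rx_benefit": pd_benefit(vals["WF"], vals["Rx"], vals["postRxWF"]),
            }
        )
    return pd.DataFrame(rows)


def analysis_window(burn_dates: list[dt.date], lag_days: int = 2) -> list[dt.date]:
    """Union of each burn date and the following ``lag_days`` days, sorted.

    Smoke transport within a regional domain typically lasts under two
    days, so exposures are analyzed on burn days plus a 2-day tail.
    """
    if lag_days < 0:
        raise ValueError("lag_days must be nonnegative")
    days: set[dt.date] = set()
    for d in burn_dates:
        for k in range(lag_days + 1):
            days.add(d + dt.timedelta(days=k))
    return sorted(days)
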