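"""Prescribed-burn unit delineation on raster landscapes.

Burn units are bounded by existing firebreaks — open water, barren land,
and developed corridors (roads, railways) in the land-cover raster.
Connected burnable regions larger than the per-day area limit
(1000 acres by default, a common risk-management guideline) are split
along gentle-slope corridors: fire spreads faster upslope through
preheating, so internal boundaries are routed where slope < 20 degrees.
The boundary path itself is found with uniform-cost search over the
raster, preceded by a binary dilation that simplifies the firebreak
boundary.

Cost model of the search: stepping onto a target (e.g. gentle-slope)
cell costs 1, onto a non-target cell 1 + ``off_target_penalty``; diagonal
steps are scaled by sqrt(2).  Ties are broken by lexicographic (row, col)
expansion order, making paths bit-reproducible.
"""

from __future__ import annotations

import datetime as dt
import heapq
import json
import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from shapely.geometry import box, mapping
from shapely.ops import unary_union

from .grid import RasterGrid

logger = logging.getLogger(__name__)

__all__ = [
    "FirebreakSpec",
    "BurnUnit",
    "BurnPlan",
    "firebreak_mask",
    "dilate",
    "uniform_cost_boundary",
    "partition_units",
    "zigzag_schedule",
    "polygonize",
    "plan_to_geojson",
]

SQRT2 = math.sqrt(2.0)

#: 8-connected neighbor offsets in lexicographic (row, col) order.
NEIGHBORS_8 = (
    (-1, -1), (-1, 0), (-1, 1),
    (0, -1), (0, 1),
    (1, -1), (1, 0), (1, 1),
)

STRUCT_8 = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class FirebreakSpec:
    """What counts as a firebreak and how large a unit may be."""

    firebreak_classes: frozenset = frozenset()
    slope_threshold_deg: float = 20.0
    max_unit_area_acres: float = 1000.0
    dilation_radius: int = 1

    def __post_init__(self) -> None:
        if not self.firebreak_classes:
            raise ValueError("firebreak_classes must be nonempty")
        if not self.slope_threshold_deg > 0:
            raise ValueError("slope_threshold_deg must be positive")
        if not self.max_unit_area_acres > 0:
            raise ValueError("max_unit_area_acres must be positive")
        if self.dilation_radius < 0:
            raise ValueError("dilation_radius must be nonnegative")


@dataclass
class BurnUnit:
    """A contiguous burnable parcel ignited as one prescribed fire."""

    unit_id: int
    cells: np.ndarray  # (n, 2) int array of (row, col)
    area_acres: float
    boundary: object | None = None  # shapely Polygon, filled by polygonize
    burn_date: dt.date | None = None
    oversize_flag: bool = False

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def centroid_rc(self) -> tuple[float, float]:
        return float(self.cells[:, 0].mean()), float(self.cells[:, 1].mean())


@dataclass
class BurnPlan:
    """Ordered burn units; list order is the burn sequence, one date each."""

    units: list[BurnUnit]

    def __post_init__(self) -> None:
        dates = [u.burn_date for u in self.units]
        if any(d is None for d in dates):
            raise ValueError("every unit in a plan needs a burn date")
        if any(b <= a for a, b in zip(dates, dates[1:])):
            raise ValueError("burn dates must be strictly increasing along the plan order")

    def __len__(self) -> int:
        return len(self.units)

    @property
    def dates(self) -> list[dt.date]:
        return [u.burn_date for u in self.units]


def firebreak_mask(landcover: RasterGrid, spec: FirebreakSpec) -> RasterGrid:
    """Binary raster: 1 where the land-cover class is a firebreak."""
    codes = np.asarray(sorted(spec.firebreak_classes))
    mask = np.isin(landcover.values, codes)
    return landcover.with_values(mask.astype(np.uint8))


def dilate(mask: RasterGrid, radius_cells: int) -> RasterGrid:
    """Binary dilation with a (2r+1) x (2r+1) square structuring element."""
    if radius_cells < 0:
        raise ValueError("radius_cells must be nonnegative")
    if radius_cells == 0:
        return mask.with_values(mask.values.astype(np.uint8))
    size = 2 * radius_cells + 1
    out = ndimage.binary_dilation(mask.values.astype(bool), structure=np.ones((size, size), bool))
    return mask.with_values(out.astype(np.uint8))


def _step_cost(target: np.ndarray, r: int, c: int, diagonal: bool, penalty: float) -> float:
    base = SQRT2 if diagonal else 1.0
    if target[r, c]:
        return base
    if math.isinf(penalty):
        return math.inf
    return base * (1.0 + penalty)


def uniform_cost_boundary(
    target: RasterGrid | np.ndarray,
    start: tuple[int, int],
    end: tuple[int, int],
    off_target_penalty: float = 1000.0,
    allowed: np.ndarray | None = None,
) -> tuple[list[tuple[int, int]], float]:
    """Minimum-cost 8-connected path between two cells, hugging target cells.

    Parameters
    ----------
    target
        Binary raster (or array) of the cells the path should follow.
    start, end
        Distinct (row, col) cells inside the grid.
    off_target_penalty
        Additional multiplicative step cost off the target set.  ``inf``
        forbids off-target steps entirely.
    allowed
        Optional binary array restricting the search to a region (used
        when splitting a single connected component).

    Returns
    -------
    (path, cost) where path is a simple list of (row, col) cells from
    start to end and cost is the sum of per-step costs.

    Raises
    ------
    ValueError on bad endpoints; RuntimeError when no finite-cost path
    exists.
    """
    tgt = target.values if isinstance(target, RasterGrid) else np.asarray(target)
    tgt = tgt.astype(bool)
    n_rows, n_cols = tgt.shape
    for name, (r, c) in (("start", start), ("end", end)):
        if not (0 <= r < n_rows and 0 <= c < n_cols):
            raise ValueError(f"{name} cell {(r, c)} outside the grid")
    if tuple(start) == tuple(end):
        raise ValueError("start and end must differ")
    if allowed is not None:
        allowed = np.asarray(allowed, dtype=bool)
        if not (allowed[start] and allowed[end]):
            raise ValueError("start/end outside the allowed region")

    dist = np.full((n_rows, n_cols), np.inf)
    prev = np.full((n_rows, n_cols, 2), -1, dtype=np.int32)
    dist[start] = 0.0
    # heap keyed by (cost, row, col): lexicographic tie-break for determinism
    heap: list[tuple[float, int, int]] = [(0.0, start[0], start[1])]
    done = np.zeros((n_rows, n_cols), dtype=bool)
    while heap:
        d, r, c = heapq.heappop(heap)
        if done[r, c]:
            continue
        done[r, c] = True
        if (r, c) == tuple(end):
            break
        for dr, dc in NEIGHBORS_8:
            nr, nc = r + dr, c + dc
            if not (0 <= nr < n_rows and 0 <= nc < n_cols) or done[nr, nc]:
                continue
            if allowed is not None and not allowed[nr, nc]:
                continue
            step = _step_cost(tgt, nr, nc, dr != 0 and dc != 0, off_target_penalty)
            nd = d + step
            if nd < dist[nr, nc]:
                dist[nr, nc] = nd
                prev[nr, nc] = (r, c)
                heapq.heappush(heap, (nd, nr, nc))
    if not np.isfinite(dist[end]):
        raise RuntimeError(f"no finite-cost path from {start} to {end}")
    path = [tuple(end)]
    while path[-1] != tuple(start):
        r, c = path[-1]
        path.append(tuple(int(v) for v in prev[r, c]))
    path.reverse()
    return path, float(dist[end])


def _thicken_to_4_connected(path: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Insert an orthogonal cell at each diagonal step.

    An 8-connected chain does not block 8-connected passage (two regions
    can touch diagonally across it); a 4-connected chain does.
    """
    out: list[tuple[int, int]] = []
    for (r0, c0), (r1, c1) in zip(path, path[1:]):
        out.append((r0, c0))
        if r1 != r0 and c1 != c0:
            out.append((r0, c1))
    out.append(path[-1])
    return out


def _perimeter_cells(comp: np.ndarray) -> np.ndarray:
    """Cells of a component mask with at least one 8-neighbor outside it."""
    interior = ndimage.binary_erosion(comp, structure=STRUCT_8, border_value=0)
    return np.argwhere(comp & ~interior)


def _split_endpoints(
    comp: np.ndarray, gentle: np.ndarray
) -> tuple[tuple[int, int], tuple[int, int]] | None:
    """Pick the two perimeter cells maximizing separation along the
    component's principal axis, snapped to gentle-slope perimeter cells
    when any exist."""
    cells = np.argwhere(comp).astype(float)
    centered = cells - cells.mean(axis=0)
    cov = centered.T @ centered / len(cells)
    eigvals, eigvecs = np.linalg.eigh(cov)
    axis = eigvecs[:, int(np.argmax(eigvals))]
    perim = _perimeter_cells(comp)
    if len(perim) < 2:
        return None
    proj = (perim - cells.mean(axis=0)) @ axis
    a = perim[int(np.argmin(proj))]
    b = perim[int(np.argmax(proj))]
    gentle_perim = perim[gentle[perim[:, 0], perim[:, 1]]]
    if len(gentle_perim) >= 2:
        da = np.abs(gentle_perim - a).max(axis=1)  # Chebyshev snap distance
        db = np.abs(gentle_perim - b).max(axis=1)
        a = gentle_perim[int(np.argmin(da))]
        ib = int(np.argmin(db))
        if tuple(gentle_perim[ib]) == tuple(a):
            db[ib] = np.iinfo(np.int64).max
            ib = int(np.argmin(db))
        b = gentle_perim[ib]
    if tuple(a) == tuple(b):
        return None
    return (int(a[0]), int(a[1])), (int(b[0]), int(b[1]))


def partition_units(
    landcover: RasterGrid,
    slope: RasterGrid,
    spec: FirebreakSpec,
    off_target_penalty: float = 1000.0,
    max_split_depth: int = 10,
) -> list[BurnUnit]:
    """Delineate burn units bounded by (dilated) firebreaks.

    Oversize 8-connected components are split recursively by a
    uniform-cost boundary routed through gentle-slope cells between the
    two perimeter cells farthest apart along the component's principal
    axis.  Split-path cells become internal firebreak and do not burn.
    Components that cannot be brought under the area limit are returned
    whole with ``oversize_flag=True`` — mirroring real plans, where the
    occasional unit exceeds the guideline when no corridor exists.
    """
    if not landcover.same_geometry(slope):
        raise ValueError("landcover and slope rasters must share geometry")
    fb = dilate(firebreak_mask(landcover, spec), spec.dilation_radius)
    burnable = ~fb.values.astype(bool)
    cell_acres = landcover.cell_area_acres
    max_cells = spec.max_unit_area_acres / cell_acres
    gentle = slope.values < spec.slope_threshold_deg

    if not burnable.any():
        logger.warning("no burnable cells after firebreak masking")
        return []

    labels, n = ndimage.label(burnable, structure=STRUCT_8)
    queue: list[tuple[np.ndarray, int]] = [(labels == i, 0) for i in range(1, n + 1)]
    finished: list[tuple[np.ndarray, bool]] = []

    while queue:
        comp, depth = queue.pop()
        n_cells = int(comp.sum())
        if n_cells <= max_cells:
            finished.append((comp, False))
            continue
        if depth >= max_split_depth:
            finished.append((comp, True))
            continue
        endpoints = _split_endpoints(comp, gentle)
        if endpoints is None:
            finished.append((comp, True))
            continue
        try:
            path, _ = uniform_cost_boundary(
                gentle & comp, endpoints[0], endpoints[1], off_target_penalty, allowed=comp
            )
        except RuntimeError:
            finished.append((comp, True))
            continue
        barrier = _thicken_to_4_connected(path)
        remaining = comp.copy()
        for r, c in barrier:
            remaining[r, c] = False
        sub_labels, n_sub = ndimage.label(remaining, structure=STRUCT_8)
        if n_sub <= 1:
            # the path failed to disconnect the component (e.g. it hugged
            # the perimeter); treat as unsplittable rather than loop
            finished.append((comp, True))
            continue
        for i in range(1, n_sub + 1):
            queue.append((sub_labels == i, depth + 1))

    # deterministic unit ids: order by (min row, min col) of each unit
    def _key(item):
        cells = np.argwhere(item[0])
        return (int(cells[:, 0].min()), int(cells[:, 1].min()), int(cells[:, 1].max()))

    finished.sort(key=_key)
    units = []
    for uid, (comp, oversize) in enumerate(finished):
        cells = np.argwhere(comp)
        units.append(
            BurnUnit(
                unit_id=uid,
                cells=cells,
                area_acres=len(cells) * cell_acres,
                oversize_flag=oversize,
            )
        )
    for u in units:
        if u.oversize_flag:
            logger.info("unit %d left oversize at %.0f acres", u.unit_id, u.area_acres)
    return units


def _total_path_length(units: list[BurnUnit]) -> float:
    cents = [u.centroid_rc() for u in units]
    return float(
        sum(math.hypot(b[0] - a[0], b[1] - a[1]) for a, b in zip(cents, cents[1:]))
    )


def zigzag_schedule(
    units: list[BurnUnit],
    dates: list[dt.date],
    n_bands: int | None = None,
) -> BurnPlan:
    """Order units serpentine by centroid row-band and assign dates.

    Units are binned into horizontal bands by centroid row; odd bands are
    traversed right-to-left, producing the "zigzag" sequence that keeps
    consecutive burns close together.  If (rarely) the caller's input
    order is already strictly shorter in total consecutive-centroid
    distance, the input order is kept.
    """
    if len(dates) < len(units):
        raise ValueError(
            f"need at least {len(units)} dates, got {len(dates)} "
            f"(short by {len(units) - len(dates)})"
        )
    if not units:
        return BurnPlan([])
    dates = sorted(dates)[: len(units)]
    rows = np.array([u.centroid_rc()[0] for u in units])
    cols = np.array([u.centroid_rc()[1] for u in units])
    if n_bands is None:
        n_bands = max(1, math.ceil(math.sqrt(len(units))))
    r0, r1 = rows.min(), rows.max()
    band_h = (r1 - r0) / n_bands if r1 > r0 else 1.0
    bands = np.minimum(((rows - r0) / band_h).astype(int), n_bands - 1)

    order = sorted(
        range(len(units)),
        key=lambda i: (
            bands[i],
            cols[i] if bands[i] % 2 == 0 else -cols[i],
            rows[i],
            units[i].unit_id,
        ),
    )
    serpentine = [units[i] for i in order]
    chosen = serpentine if _total_path_length(serpentine) <= _total_path_length(units) else list(units)
    import copy

    scheduled = []
    for u, d in zip(chosen, dates):
        u2 = copy.copy(u)
        u2.burn_date = d
        scheduled.append(u2)
    return BurnPlan(scheduled)


def polygonize(unit: BurnUnit, grid: RasterGrid):
    """Exterior polygon of a unit in map coordinates (traces cell edges)."""
    s = grid.cell_size_m
    boxes = [
        box(
            grid.origin_x + c * s,
            grid.origin_y - (r + 1) * s,
            grid.origin_x + (c + 1) * s,
            grid.origin_y - r * s,
        )
        for r, c in unit.cells
    ]
    # zero-tolerance simplification drops collinear edge vertices only
    poly = unary_union(boxes).simplify(0)
    unit.boundary = poly
    return poly


def plan_to_geojson(plan: BurnPlan, grid: RasterGrid, path=None) -> dict:
    """GeoJSON FeatureCollection of the plan's unit polygons."""
    features = []
    for u in plan.units:
        poly = u.boundary if u.boundary is not None else polygonize(u, grid)
        features.append(
            {
                "type": "Feature",
                "geometry": mapping(poly),
                "properties": {
                    "unit_id": u.unit_id,
                    "area_acres": u.area_acres,
                    "burn_date": u.burn_date.isoformat() if u.burn_date else None,
                    "oversize_flag": u.oversize_flag,
                },
            }
        )
    collection = {"type": "FeatureCollection", "features": features}
    if path is not None:
        with open(path, "w") as fh:
            json.dump(collection, fh)
    return collection
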