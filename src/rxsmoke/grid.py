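"""Raster grid container shared by every gridded layer in the pipeline.

All layers in one scenario (land cover, slope, population, concentration)
live on axis-aligned regular grids.  Row 0 is the northern edge; cell
centers sit at half-cell offsets from the outer corner of cell (0, 0),
whose map coordinates are ``(origin_x, origin_y)`` (x increases east,
y increases north, so rows advance southward).

Rasters are read and written as ESRI ASCII grids, a plain-text format
understood by every GIS.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

#: Exact international acre in square metres.
ACRE_M2 = 4046.8564224


@dataclass(frozen=True)
class GridGeometry:
    """Geometry of a regular raster: shape, cell size and placement."""

    n_rows: int
    n_cols: int
    cell_size_m: float
    origin_x: float = 0.0
    origin_y: float = 0.0

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and column")
        if not (self.cell_size_m > 0):
            raise ValueError("cell_size_m must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def cell_area_m2(self) -> float:
        return self.cell_size_m**2

    @property
    def cell_area_acres(self) -> float:
        return self.cell_area_m2 / ACRE_M2

    def x_centers(self) -> np.ndarray:
        """East-west cell-center coordinates, one per column."""
        return self.origin_x + (np.arange(self.n_cols) + 0.5) * self.cell_size_m

    def y_centers(self) -> np.ndarray:
        """North-south cell-center coordinates, one per row (descending)."""
        return self.origin_y - (np.arange(self.n_rows) + 0.5) * self.cell_size_m

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        return (
            self.origin_x + (col + 0.5) * self.cell_size_m,
            self.origin_y - (row + 0.5) * self.cell_size_m,
        )

    def contains_point(self, x: float, y: float) -> bool:
        return (
            self.origin_x <= x <= self.origin_x + self.n_cols * self.cell_size_m
            and self.origin_y - self.n_rows * self.cell_size_m <= y <= self.origin_y
        )

    def matches(self, other: "GridGeometry", tol: float = 1e-6) -> bool:
        return (
            self.n_rows == other.n_rows
            and self.n_cols == other.n_cols
            and math.isclose(self.cell_size_m, other.cell_size_m, rel_tol=tol)
            and math.isclose(self.origin_x, other.origin_x, abs_tol=tol * max(1.0, self.cell_size_m))
            and math.isclose(self.origin_y, other.origin_y, abs_tol=tol * max(1.0, self.cell_size_m))
        )


@dataclass
class RasterGrid:
    """A 2D array of values plus its geometry and nodata sentinel."""

    values: np.ndarray
    cell_size_m: float
    origin_x: float = 0.0
    origin_y: float = 0.0
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("raster values must be a 2D array")
        # geometry validation
        GridGeometry(*self.values.shape, self.cell_size_m, self.origin_x, self.origin_y)

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def geometry(self) -> GridGeometry:
        return GridGeometry(
            self.n_rows, self.n_cols, self.cell_size_m, self.origin_x, self.origin_y
        )

    @property
    def cell_area_acres(self) -> float:
        return self.geometry.cell_area_acres

    def same_geometry(self, other: "RasterGrid", tol: float = 1e-6) -> bool:
        return self.geometry.matches(other.geometry, tol)

    def with_values(self, values: np.ndarray) -> "RasterGrid":
        """A raster on the same geometry carrying different values."""
        values = np.asarray(values)
        if values.shape != self.values.shape:
            raise ValueError("replacement values must keep the raster shape")
        return replace(self, values=values)

    @classmethod
    def from_geometry(
        cls, geom: GridGeometry, values: np.ndarray, nodata: float = -9999.0
    ) -> "RasterGrid":
        values = np.asarray(values)
        if values.shape != geom.shape:
            raise ValueError(f"values shape {values.shape} != geometry shape {geom.shape}")
        return cls(values, geom.cell_size_m, geom.origin_x, geom.origin_y, nodata)


def write_ascii_grid(grid: RasterGrid, path) -> None:
    """Write a raster as an ESRI ASCII grid (plain text)."""
    yll = grid.origin_y - grid.n_rows * grid.cell_size_m
    header = (
        f"ncols {grid.n_cols}\n"
        f"nrows {grid.n_rows}\n"
        f"xllcorner {grid.origin_x!r}\n"
        f"yllcorner {yll!r}\n"
        f"cellsize {grid.cell_size_m!r}\n"
        f"NODATA_value {grid.nodata!r}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, grid.values, fmt="%.10g")


def read_ascii_grid(path) -> RasterGrid:
    """Read an ESRI ASCII grid written by :func:`write_ascii_grid` or a GIS."""
    header: dict[str, float] = {}
    n_header = 0
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if len(parts) == 2 and parts[0][0].isalpha():
                header[parts[0].lower()] = float(parts[1])
                n_header += 1
            else:
                break
    required = {"ncols", "nrows", "cellsize"}
    if not required <= header.keys():
        raise ValueError(f"ASCII grid header missing {required - header.keys()}")
    values = np.loadtxt(path, skiprows=n_header)
    values = np.atleast_2d(values)
    cell = header["cellsize"]
    n_rows = int(header["nrows"])
    # ESRI anchors at the lower-left corner; our origin is the upper-left.
    if "xllcorner" in header:
        x0 = header["xllcorner"]
        y0 = header["yllcorner"] + n_rows * cell
    else:  # center-anchored variant
        x0 = header["xllcenter"] - cell / 2
        y0 = header["yllcenter"] - cell / 2 + n_rows * cell
    nodata = header.get("nodata_value", -9999.0)
    return RasterGrid(values, cell, x0, y0, nodata)
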