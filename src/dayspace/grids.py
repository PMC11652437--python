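"""Planar analysis grids and Esri ASCII raster I/O.

All coordinates are metres on a local planar CRS. A :class:`GridSpec`
describes a regular grid of square cells; cell ``(r, c)`` covers the
half-open square ``[origin_x + c*s, origin_x + (c+1)*s) x
[origin_y + r*s, origin_y + (r+1)*s)`` with row 0 the *southernmost*
row. Activity-space surfaces and environmental layers share a
GridSpec so weighted overlays never resample.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["GridSpec", "make_grid_spec", "write_esri_ascii", "read_esri_ascii"]


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a regular square-celled analysis grid."""

    origin_x: float  # lower-left corner, metres
    origin_y: float
    cell_size: float  # metres, default grids use 50 m
    nrows: int
    ncols: int

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.nrows < 1 or self.ncols < 1:
            raise ValueError("grid must have at least one row and column")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.nrows, self.ncols)

    @property
    def x_centers(self) -> np.ndarray:
        return self.origin_x + (np.arange(self.ncols) + 0.5) * self.cell_size

    @property
    def y_centers(self) -> np.ndarray:
        return self.origin_y + (np.arange(self.nrows) + 0.5) * self.cell_size

    def center_mesh(self) -> tuple[np.ndarray, np.ndarray]:
        """Arrays (nrows, ncols) of cell-center x and y coordinates."""
        cx, cy = np.meshgrid(self.x_centers, self.y_centers)
        return cx, cy

    def cell_of(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        """(row, col) of the cell containing each point (half-open cells)."""
        col = np.floor((np.asarray(x) - self.origin_x) / self.cell_size).astype(int)
        row = np.floor((np.asarray(y) - self.origin_y) / self.cell_size).astype(int)
        return row, col

    def contains_points(self, x, y) -> np.ndarray:
        row, col = self.cell_of(x, y)
        return (row >= 0) & (row < self.nrows) & (col >= 0) & (col < self.ncols)

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the gridded area."""
        return (
            self.origin_x,
            self.origin_y,
            self.origin_x + self.ncols * self.cell_size,
            self.origin_y + self.nrows * self.cell_size,
        )


def make_grid_spec(
    extent: tuple[float, float, float, float],
    cell_size: float = 50.0,
    pad: float = 0.0,
) -> GridSpec:
    """Build a GridSpec covering ``extent`` expanded by ``pad`` metres.

    The origin is snapped *down* to a multiple of ``cell_size`` (and the
    far corner up), so independently built grids over overlapping
    extents align cell-for-cell. ``pad`` defaults to 0; callers that
    smooth point mass (e.g. a kernel surface) pass pad >= bandwidth so
    no mass is clipped.
    """
    if cell_size <= 0:
        raise ValueError("cell_size must be positive")
    xmin, ymin, xmax, ymax = extent
    if not (xmax > xmin and ymax > ymin):
        raise ValueError("extent is degenerate")
    x0 = math.floor((xmin - pad) / cell_size) * cell_size
    y0 = math.floor((ymin - pad) / cell_size) * cell_size
    x1 = math.ceil((xmax + pad) / cell_size) * cell_size
    y1 = math.ceil((ymax + pad) / cell_size) * cell_size
    return GridSpec(
        origin_x=x0,
        origin_y=y0,
        cell_size=cell_size,
        nrows=int(round((y1 - y0) / cell_size)),
        ncols=int(round((x1 - x0) / cell_size)),
    )


def write_esri_ascii(path, grid: GridSpec, values: np.ndarray, nodata: float = -9999.0) -> None:
    """Write a (nrows, ncols) array as an Esri ASCII grid.

    ``values`` is row-0-south (our convention); the file format stores
    the northernmost row first, so rows are flipped on write. NaNs are
    written as the nodata value.
    """
    values = np.asarray(values, dtype=float)
    if values.shape != grid.shape:
        raise ValueError(f"values shape {values.shape} != grid shape {grid.shape}")
    out = np.where(np.isnan(values), nodata, values)
    with open(path, "w") as fh:
        fh.write(f"ncols {grid.ncols}\n")
        fh.write(f"nrows {grid.nrows}\n")
        fh.write(f"xllcorner {grid.origin_x:.6f}\n")
        fh.write(f"yllcorner {grid.origin_y:.6f}\n")
        fh.write(f"cellsize {grid.cell_size:.6f}\n")
        fh.write(f"NODATA_value {nodata}\n")
        for r in range(grid.nrows - 1, -1, -1):
            fh.write(" ".join(format(v, ".10g") for v in out[r]) + "\n")


def read_esri_ascii(path) -> tuple[GridSpec, np.ndarray]:
    """Read an Esri ASCII grid; returns (GridSpec, values) with nodata as NaN."""
    header: dict[str, float] = {}
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            key = parts[0].lower()
            if key in {"ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"}:
                header[key] = float(parts[1])
            else:
                rows.append([float(v) for v in parts])
    required = {"ncols", "nrows", "xllcorner", "yllcorner", "cellsize"}
    if not required.issubset(header):
        raise ValueError(f"{path}: missing Esri ASCII header keys {required - set(header)}")
    grid = GridSpec(
        origin_x=header["xllcorner"],
        origin_y=header["yllcorner"],
        cell_size=header["cellsize"],
        nrows=int(header["nrows"]),
        ncols=int(header["ncols"]),
    )
    values = np.array(rows, dtype=float)
    if values.shape != grid.shape:
        raise ValueError(f"{path}: data shape {values.shape} != header shape {grid.shape}")
    values = values[::-1]  # file is north-first; flip to row-0-south
    nodata = header.get("nodata_value")
    if nodata is not None:
        values = np.where(values == nodata, np.nan, values)
    return grid, values
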