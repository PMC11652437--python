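"""Daily activity spaces as time-weight surfaces on the analysis grid.

A valid GPS day becomes a :class:`TimeWeightGrid`: per-cell weights
that sum to 1 and read as fractions of the day's time spent in (or
attributed to) each 50 m cell. Three constructions are provided:

``kde_surface``
    The primary method. Each 10-s epoch spreads one unit of time mass
    over nearby cell centers with a quartic (biweight) kernel of
    bandwidth 250 m (sensitivity variant: 100 m).
``daily_path_surface``
    The day's route polyline buffered by a fixed radius (250 m);
    covered cells share weight uniformly.
``residential_buffer_surface``
    A static home-neighborhood comparator: a euclidean disc or a
    street-network service area (800/1600 m).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import shapely
from shapely.geometry import LineString, Point
from shapely.ops import unary_union

from . import network as net
from .gps import GpsTrack
from .grids import GridSpec, make_grid_spec  # noqa: F401  (re-exported)

WEIGHT_TOL = 1e-9

__all__ = [
    "TimeWeightGrid",
    "make_grid_spec",
    "kde_surface",
    "daily_path_surface",
    "residential_buffer_surface",
]


@dataclass
class TimeWeightGrid:
    """Activity-space surface: per-cell fractions of one day's time."""

    grid: GridSpec
    weights: np.ndarray  # (nrows, ncols), >= 0, sums to 1
    method: str  # kde | daily_path | residential_buffer
    bandwidth_or_radius: float  # metres

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != self.grid.shape:
            raise ValueError("weights shape does not match grid")
        if np.any(self.weights < 0):
            raise ValueError("weights must be non-negative")
        total = float(self.weights.sum())
        if abs(total - 1.0) > WEIGHT_TOL:
            raise ValueError(f"weights must sum to 1 (got {total!r})")


def write_surface(surface: TimeWeightGrid, path) -> None:
    """Write a surface as an Esri ASCII grid plus a JSON sidecar.

    The sidecar (``<path>.meta.json``) records the construction method
    and its bandwidth/radius so a surface on disk is self-describing.
    """
    import json
    from pathlib import Path

    from .grids import write_esri_ascii

    path = Path(path)
    write_esri_ascii(path, surface.grid, surface.weights)
    with open(path.with_suffix(path.suffix + ".meta.json"), "w") as fh:
        json.dump(
            {"method": surface.method, "bandwidth_or_radius": surface.bandwidth_or_radius},
            fh,
        )


def _normalized(grid: GridSpec, weights: np.ndarray, method: str, scale: float) -> TimeWeightGrid:
    total = weights.sum()
    if total <= 0:
        raise ValueError(f"{method} surface has no mass on the grid")
    return TimeWeightGrid(grid, weights / total, method, scale)


def kde_surface(
    track: GpsTrack,
    grid: GridSpec,
    bandwidth: float = 250.0,
    kernel: str = "quartic",
) -> TimeWeightGrid:
    """Time-weighted kernel density surface of one GPS day.

    Every epoch (observed or imputed) carries one unit of time. Its
    mass is spread over cell centers within ``bandwidth`` by the
    quartic kernel ``(1 - (d/h)^2)^2`` (or a Gaussian with sigma = h/2
    truncated at h), normalized per epoch so edge truncation cannot
    distort relative time weights, then accumulated and renormalized.
    """
    if len(track) == 0:
        raise ValueError("empty track")
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    s = grid.cell_size
    rad = int(np.ceil(bandwidth / s)) + 1
    dr, dc = np.meshgrid(np.arange(-rad, rad + 1), np.arange(-rad, rad + 1), indexing="ij")
    dr, dc = dr.ravel(), dc.ravel()

    row0, col0 = grid.cell_of(track.x, track.y)
    rows = row0[:, None] + dr[None, :]
    cols = col0[:, None] + dc[None, :]
    cx = grid.origin_x + (cols + 0.5) * s
    cy = grid.origin_y + (rows + 0.5) * s
    d2 = (cx - track.x[:, None]) ** 2 + (cy - track.y[:, None]) ** 2

    u = d2 / bandwidth**2
    if kernel == "quartic":
        k = np.where(u < 1.0, (1.0 - u) ** 2, 0.0)
    elif kernel == "gaussian":
        sigma2 = (bandwidth / 2.0) ** 2
        k = np.where(u < 1.0, np.exp(-0.5 * d2 / sigma2), 0.0)
    else:
        raise ValueError(f"unknown kernel {kernel!r}")

    inside = (rows >= 0) & (rows < grid.nrows) & (cols >= 0) & (cols < grid.ncols)
    k = np.where(inside, k, 0.0)
    totals = k.sum(axis=1)
    if np.any(totals <= 0):
        raise ValueError("an epoch's kernel support lies entirely off-grid; pad the grid by >= bandwidth")
    k /= totals[:, None]

    weights = np.zeros(grid.shape)
    flat = np.where(inside, rows * grid.ncols + cols, 0)
    np.add.at(weights.ravel(), flat.ravel(), k.ravel())
    return _normalized(grid, weights, "kde", bandwidth)


def _route_pieces(track: GpsTrack, gap_break_min: float) -> list:
    """Split the day's trajectory at observed gaps longer than ``gap_break_min``."""
    breaks = np.flatnonzero(np.diff(track.t) > gap_break_min * 60.0)
    pieces = []
    start = 0
    for b in np.append(breaks, len(track) - 1):
        idx = slice(start, int(b) + 1)
        pts = np.column_stack([track.x[idx], track.y[idx]])
        pieces.append(LineString(pts) if len(pts) >= 2 else Point(pts[0]))
        start = int(b) + 1
    return pieces


def _uniform_over(geom, grid: GridSpec, method: str, scale: float) -> TimeWeightGrid:
    cx, cy = grid.center_mesh()
    covered = shapely.intersects_xy(geom, cx.ravel(), cy.ravel()).reshape(grid.shape)
    return _normalized(grid, covered.astype(float), method, scale)


def daily_path_surface(
    track: GpsTrack,
    grid: GridSpec,
    radius: float = 250.0,
    gap_break_min: float = 5.0,
) -> TimeWeightGrid:
    """Daily-path-area surface: the route polyline buffered by ``radius``.

    Successive points are connected in time order; observed gaps longer
    than ``gap_break_min`` minutes split the route so no corridor is
    fabricated across unobserved periods. Cells whose centers fall in
    the buffer share weight uniformly. A single-epoch track degenerates
    to a disc.
    """
    if len(track) == 0:
        raise ValueError("empty track")
    if radius <= 0:
        raise ValueError("radius must be positive")
    buffer = unary_union([p.buffer(radius, quad_segs=32) for p in _route_pieces(track, gap_break_min)])
    return _uniform_over(buffer, grid, "daily_path", radius)


def residential_buffer_surface(
    home: tuple[float, float],
    grid: GridSpec,
    radius: float = 800.0,
    mode: str = "euclidean",
    streets=None,
    block_width: float | None = None,
) -> TimeWeightGrid:
    """Residential-neighborhood surface around the home location.

    ``euclidean`` mode covers the disc of ``radius`` metres; ``network``
    mode covers the street-network service area — every point within
    ``radius`` metres of walking distance from the node nearest home —
    buffered by one block width. Weights are uniform over covered cells.
    """
    xmin, ymin, xmax, ymax = grid.extent
    if not (xmin <= home[0] <= xmax and ymin <= home[1] <= ymax):
        raise ValueError("home lies outside the grid")
    if mode == "euclidean":
        geom = Point(home).buffer(radius, quad_segs=64)
    elif mode == "network":
        if streets is None:
            raise ValueError("network mode requires the street segment set")
        graph = net.build_street_graph(streets)
        source = net.snap_to_node(graph, home)
        dists = net.network_node_distances(graph, source)
        pieces = net.reachable_subsegments(graph, dists, radius)
        if not pieces:
            raise ValueError("no street within reach of home")
        if block_width is None:
            block_width = float(np.median([d["weight"] for _, _, d in graph.edges(data=True)]))
        geom = unary_union(pieces).buffer(block_width, quad_segs=16)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return _uniform_over(geom, grid, "residential_buffer", radius)
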