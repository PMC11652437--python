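"""Environmental layers on the analysis grid and daily exposure metrics.

Four daily metrics are evaluated by the weighted-sum overlay of an
activity-space surface against a gridded environmental layer: street
greenspace coverage (%), walking distance to the nearest park
entrance (m), any park/open-space exposure (yes/no), and the
walkability index (1-20). A cell's surface weight is its fraction of
the day's time, so the weighted sum is the time-weighted daily
exposure; the park metric is instead binarized as any positive
overlap with park cells.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

import numpy as np
import shapely
from scipy.spatial import cKDTree
from shapely.geometry import LineString
from shapely.ops import unary_union

from . import network as net
from .activityspace import (
    TimeWeightGrid,
    daily_path_surface,
    kde_surface,
    residential_buffer_surface,
)
from .config import ActivitySpaceParams
from .gps import GpsTrack
from .grids import GridSpec

LAYER_RANGES = {
    "green_pct": (0.0, 100.0),
    "park_distance_m": (0.0, np.inf),
    "park_indicator": (0.0, 1.0),
    "walkability": (1.0, 20.0),
}

__all__ = [
    "EnvLayer",
    "DayExposureRecord",
    "rasterize_street_greenspace",
    "park_distance_layer",
    "rasterize_parks",
    "rasterize_walkability",
    "weighted_exposure",
    "parks_any_exposure",
    "derive_day_exposures",
]


@dataclass
class EnvLayer:
    """One gridded environmental variable; NaN cells are nodata."""

    grid: GridSpec
    values: np.ndarray
    variable: str  # green_pct | park_distance_m | park_indicator | walkability

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError("values shape does not match grid")
        if self.variable not in LAYER_RANGES:
            raise ValueError(f"unknown layer variable {self.variable!r}")
        lo, hi = LAYER_RANGES[self.variable]
        defined = self.values[~np.isnan(self.values)]
        if defined.size and (defined.min() < lo - 1e-9 or defined.max() > hi + 1e-9):
            raise ValueError(f"{self.variable} values outside [{lo}, {hi}]")

    @property
    def defined(self) -> np.ndarray:
        return ~np.isnan(self.values)


@dataclass
class DayExposureRecord:
    """The four daily exposure metrics for one person-day and method."""

    participant_id: str
    wave: str
    date: dt.date
    day_type: str
    method: str
    bandwidth_or_radius: float
    green_pct: float
    park_distance_m: float
    parks_any: bool
    walkability: float


def _segment_parts(streets) -> list[tuple[float, float, float, float]]:
    parts = []
    for seg in streets:
        coords = list(seg.coords) if isinstance(seg, LineString) else list(seg)
        for (x0, y0), (x1, y1) in zip(coords[:-1], coords[1:]):
            parts.append((float(x0), float(y0), float(x1), float(y1)))
    return parts


def rasterize_street_greenspace(
    streets,
    green_pct,
    grid: GridSpec,
    buffer_m: float = 25.0,
    length_radius: float = 50.0,
) -> EnvLayer:
    """Grid per-street-segment greenspace percentages.

    A cell is on the walkable street network iff its center lies within
    ``buffer_m`` (25 m) of at least one segment; such cells take the
    length-weighted mean green % of nearby segments, each weighted by
    its length within ``length_radius`` (50 m) of the cell center.
    Off-network cells are nodata.
    """
    streets = list(streets)
    green = np.asarray(green_pct, dtype=float)
    if not streets:
        raise ValueError("empty street set")
    if len(streets) != len(green):
        raise ValueError("one green % per street required")
    if np.any((green < 0) | (green > 100)):
        raise ValueError("green % must lie in [0, 100]")

    xs, ys = grid.x_centers, grid.y_centers
    num = np.zeros(grid.shape)
    den = np.zeros(grid.shape)
    mindist = np.full(grid.shape, np.inf)
    s = grid.cell_size
    parts = [(p, g) for seg, g in zip(streets, green) for p in _segment_parts([seg])]
    for (x0, y0, x1, y1), g in parts:
        # candidate cells: bounding box of the segment grown by length_radius
        c0 = max(0, int(np.floor((min(x0, x1) - length_radius - grid.origin_x) / s)))
        c1 = min(grid.ncols - 1, int(np.floor((max(x0, x1) + length_radius - grid.origin_x) / s)))
        r0 = max(0, int(np.floor((min(y0, y1) - length_radius - grid.origin_y) / s)))
        r1 = min(grid.nrows - 1, int(np.floor((max(y0, y1) + length_radius - grid.origin_y) / s)))
        if c1 < c0 or r1 < r0:
            continue
        cx, cy = np.meshgrid(xs[c0 : c1 + 1], ys[r0 : r1 + 1])
        ex, ey = x1 - x0, y1 - y0
        length = float(np.hypot(ex, ey))
        if length == 0:
            continue
        ux, uy = ex / length, ey / length
        t0 = (cx - x0) * ux + (cy - y0) * uy  # projection parameter along the segment
        dperp = np.abs(-(cx - x0) * uy + (cy - y0) * ux)
        tc = np.clip(t0, 0.0, length)
        dist = np.hypot(cx - (x0 + tc * ux), cy - (y0 + tc * uy))
        sl = np.s_[r0 : r1 + 1, c0 : c1 + 1]
        np.minimum(mindist[sl], dist, out=mindist[sl])
        # chord of the segment inside the disc of radius length_radius
        half = np.sqrt(np.maximum(length_radius**2 - dperp**2, 0.0))
        chord = np.maximum(np.minimum(t0 + half, length) - np.maximum(t0 - half, 0.0), 0.0)
        chord = np.where(dperp < length_radius, chord, 0.0)
        num[sl] += chord * g
        den[sl] += chord

    values = np.full(grid.shape, np.nan)
    on_network = (mindist <= buffer_m) & (den > 0)
    values[on_network] = num[on_network] / den[on_network]
    return EnvLayer(grid, values, "green_pct")


def park_distance_layer(entrances, grid: GridSpec, mode: str = "euclidean", streets=None) -> EnvLayer:
    """Distance (m) from each cell center to the nearest park entrance.

    ``euclidean`` is straight-line; ``network`` walks the street
    lattice: cell centers and entrances snap to their nearest street
    node and a multi-source shortest path supplies the between-node
    distance, with the two snap legs added euclidean.
    """
    pts = np.asarray([(float(p.x), float(p.y)) if hasattr(p, "x") else tuple(map(float, p)) for p in entrances])
    if pts.size == 0:
        raise ValueError("at least one park entrance required")
    cx, cy = grid.center_mesh()
    if mode == "euclidean":
        dist = np.full(grid.shape, np.inf)
        for ex, ey in pts:
            np.minimum(dist, np.hypot(cx - ex, cy - ey), out=dist)
    elif mode == "network":
        if streets is None:
            raise ValueError("network mode requires the street segment set")
        graph = net.build_street_graph(streets)
        nodes = np.array(list(graph.nodes))
        tree = cKDTree(nodes)
        snap_d, snap_i = tree.query(pts)
        import networkx as nx

        sources = {tuple(nodes[i]): float(d) for i, d in zip(snap_i, snap_d)}
        # multi-source Dijkstra seeded with the entrance->node snap legs
        g2 = graph.copy()
        g2.add_node("__src__")
        for node, d in sources.items():
            g2.add_edge("__src__", node, weight=d)
        node_d = nx.single_source_dijkstra_path_length(g2, "__src__", weight="weight")
        cell_snap_d, cell_snap_i = tree.query(np.column_stack([cx.ravel(), cy.ravel()]))
        per_node = np.array([node_d.get(tuple(n), np.inf) for n in nodes])
        dist = (cell_snap_d + per_node[cell_snap_i]).reshape(grid.shape)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return EnvLayer(grid, dist, "park_distance_m")


def rasterize_parks(park_polygons, grid: GridSpec) -> EnvLayer:
    """Binary park indicator: 1 iff the cell center lies inside any park polygon."""
    polys = list(park_polygons)
    for p in polys:
        if not p.is_valid:
            raise ValueError("invalid park polygon geometry")
    cx, cy = grid.center_mesh()
    if polys:
        union = unary_union(polys)
        inside = shapely.intersects_xy(union, cx.ravel(), cy.ravel()).reshape(grid.shape)
    else:
        inside = np.zeros(grid.shape, dtype=bool)
    return EnvLayer(grid, inside.astype(float), "park_indicator")


def rasterize_walkability(patches, scores, grid: GridSpec) -> EnvLayer:
    """Tract-level walkability scores gridded by cell-center membership.

    ``patches`` are polygons partitioning the region with scores in
    [1, 20]; a cell takes the score of the patch containing its center
    and is nodata outside all patches.
    """
    patches = list(patches)
    scores = np.asarray(scores, dtype=float)
    if len(patches) != len(scores):
        raise ValueError("one score per patch required")
    if scores.size and (scores.min() < 1 or scores.max() > 20):
        raise ValueError("walkability scores must lie in [1, 20]")
    cx, cy = grid.center_mesh()
    values = np.full(grid.shape, np.nan)
    for patch, score in zip(patches, scores):
        hit = shapely.intersects_xy(patch, cx.ravel(), cy.ravel()).reshape(grid.shape)
        values[hit] = score
    return EnvLayer(grid, values, "walkability")


def weighted_exposure(surface: TimeWeightGrid, layer: EnvLayer, nodata_policy: str = "renormalize") -> float:
    """Time-weighted daily exposure: sum over cells of weight x layer value.

    The surface and layer must share one GridSpec (no silent
    resampling). Nodata cells are handled by renormalizing the surface
    weights over defined cells (default; exposure is conditional on
    time spent where the variable exists) or by treating nodata as 0.
    """
    if surface.grid != layer.grid:
        raise ValueError("surface and layer grids differ")
    defined = layer.defined
    w = surface.weights
    if nodata_policy == "renormalize":
        wsum = w[defined].sum()
        if wsum <= 0:
            return float("nan")
        return float((w[defined] * layer.values[defined]).sum() / wsum)
    if nodata_policy == "zero":
        return float((w[defined] * layer.values[defined]).sum())
    raise ValueError(f"unknown nodata policy {nodata_policy!r}")


def parks_any_exposure(surface: TimeWeightGrid, parks: EnvLayer) -> bool:
    """Any park/open-space exposure: does any positive-weight cell sit on a park?"""
    if surface.grid != parks.grid:
        raise ValueError("surface and layer grids differ")
    return bool(np.any((surface.weights > 0) & (parks.values == 1.0)))


def build_surface(track: GpsTrack, env, params: ActivitySpaceParams, home=None) -> TimeWeightGrid:
    """Construct the configured activity-space surface on the environment grid."""
    if params.method == "kde":
        return kde_surface(track, env.grid, bandwidth=params.kde_bandwidth, kernel=params.kde_kernel)
    if params.method == "daily_path":
        return daily_path_surface(track, env.grid, radius=params.daily_path_radius,
                                  gap_break_min=params.path_gap_break)
    if params.method == "residential_buffer":
        if home is None:
            raise ValueError("residential_buffer method requires the home location")
        return residential_buffer_surface(
            home, env.grid, radius=params.residential_radius,
            mode=params.residential_mode, streets=env.streets,
        )
    raise ValueError(f"unknown activity-space method {params.method!r}")


def derive_day_exposures(
    track: GpsTrack,
    env,
    params: ActivitySpaceParams | None = None,
    home=None,
) -> DayExposureRecord:
    """All four daily exposure metrics for one valid GPS day."""
    params = params or ActivitySpaceParams()
    surface = build_surface(track, env, params, home=home)
    scale = {
        "kde": params.kde_bandwidth,
        "daily_path": params.daily_path_radius,
        "residential_buffer": params.residential_radius,
    }[params.method]
    return DayExposureRecord(
        participant_id=track.participant_id,
        wave=track.wave,
        date=track.date,
        day_type=track.day_type,
        method=params.method,
        bandwidth_or_radius=scale,
        green_pct=weighted_exposure(surface, env.greenspace_layer),
        park_distance_m=weighted_exposure(surface, env.park_distance_layer),
        parks_any=parks_any_exposure(surface, env.park_layer),
        walkability=weighted_exposure(surface, env.walkability_layer),
    )
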