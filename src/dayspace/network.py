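"""Pedestrian-network distances on a street-segment set.

Streets are planar line segments whose shared endpoints define graph
nodes; edge weights are segment lengths in metres. Used for network
park distances and residential service areas.
"""

from __future__ import annotations

import networkx as nx
import numpy as np
from shapely.geometry import LineString

__all__ = [
    "build_street_graph",
    "snap_to_node",
    "network_node_distances",
    "reachable_subsegments",
]


def build_street_graph(segments) -> nx.Graph:
    """Graph whose nodes are segment endpoints and edge weights segment lengths."""
    g = nx.Graph()
    for seg in segments:
        coords = list(seg.coords) if isinstance(seg, LineString) else list(seg)
        for (x0, y0), (x1, y1) in zip(coords[:-1], coords[1:]):
            u, v = (float(x0), float(y0)), (float(x1), float(y1))
            g.add_edge(u, v, weight=float(np.hypot(x1 - x0, y1 - y0)))
    if g.number_of_edges() == 0:
        raise ValueError("street set has no segments")
    return g


def snap_to_node(graph: nx.Graph, point) -> tuple[float, float]:
    """Nearest graph node to a point (x, y) by euclidean distance."""
    px, py = float(point[0]), float(point[1])
    nodes = np.array(list(graph.nodes))
    i = int(np.argmin((nodes[:, 0] - px) ** 2 + (nodes[:, 1] - py) ** 2))
    return tuple(nodes[i])


def network_node_distances(graph: nx.Graph, source) -> dict:
    """Shortest-path distance (metres) from ``source`` node to every reachable node."""
    return nx.single_source_dijkstra_path_length(graph, source, weight="weight")


def reachable_subsegments(graph: nx.Graph, dists: dict, budget: float) -> list[LineString]:
    """Portions of edges reachable within ``budget`` metres of the distance source.

    A point p on edge (u, v) at offset s from u is reachable iff
    ``min(d(u) + s, d(v) + (L - s)) <= budget``; the reachable portion of
    each edge is one or two sub-segments, returned as LineStrings.
    """
    pieces: list[LineString] = []
    for u, v, data in graph.edges(data=True):
        length = data["weight"]
        du = dists.get(u, np.inf)
        dv = dists.get(v, np.inf)
        if min(du, dv) > budget:
            continue
        su = min(length, budget - du) if du <= budget else -1.0  # reach from u end
        sv = min(length, budget - dv) if dv <= budget else -1.0  # reach from v end
        ux, uy = u
        vx, vy = v
        dx, dy = (vx - ux) / length, (vy - uy) / length
        if su >= 0 and sv >= 0 and su + sv >= length:
            pieces.append(LineString([u, v]))
            continue
        if su > 0:
            pieces.append(LineString([u, (ux + dx * su, uy + dy * su)]))
        if sv > 0:
            pieces.append(LineString([(vx - dx * sv, vy - dy * sv), v]))
    return pieces
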