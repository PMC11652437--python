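"""Minimal GeoJSON I/O for shapely geometries with per-feature properties."""

from __future__ import annotations

import json

from shapely.geometry import mapping, shape

__all__ = ["write_geojson", "read_geojson"]


def write_geojson(path, geometries, properties=None) -> None:
    """Write geometries (and optional per-feature property dicts) as a FeatureCollection."""
    geometries = list(geometries)
    if properties is None:
        properties = [{} for _ in geometries]
    features = [
        {"type": "Feature", "geometry": mapping(g), "properties": p}
        for g, p in zip(geometries, properties, strict=True)
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def read_geojson(path):
    """Read a FeatureCollection; returns (list of shapely geometries, list of property dicts)."""
    with open(path) as fh:
        doc = json.load(fh)
    geoms = [shape(f["geometry"]) for f in doc["features"]]
    props = [f.get("properties") or {} for f in doc["features"]]
    return geoms, props
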