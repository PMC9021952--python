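"""Minimal GeoJSON FeatureCollection I/O on top of shapely.

Layers are lists of ``Feature`` records (a shapely geometry plus a property
dict). All coordinates must be planar, in meters. Input that looks like
geographic longitude/latitude is rejected outright rather than reprojected:
at desk scale every layer is expected to share one projected CRS and silent
reprojection would hide unit errors in every downstream distance and area.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Any, Iterable, Sequence

import shapely
from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry

__all__ = ["Feature", "FeatureLayer", "read_geojson", "write_geojson"]


@dataclass
class Feature:
    geometry: BaseGeometry
    properties: dict[str, Any] = field(default_factory=dict)


class FeatureLayer:
    """An ordered collection of features, analogous to one GeoJSON file."""

    def __init__(self, features: Iterable[Feature] | None = None):
        self.features: list[Feature] = list(features or [])

    def __len__(self) -> int:
        return len(self.features)

    def __iter__(self):
        return iter(self.features)

    def __getitem__(self, i: int) -> Feature:
        return self.features[i]

    @property
    def geometries(self) -> list[BaseGeometry]:
        return [f.geometry for f in self.features]

    def codes(self, code_field: str = "code") -> list[str]:
        try:
            return [str(f.properties[code_field]) for f in self.features]
        except KeyError as exc:
            raise SchemaError(
                f"feature missing required field {code_field!r}"
            ) from exc

    def to_geojson(self) -> dict:
        return {
            "type": "FeatureCollection",
            "features": [
                {
                    "type": "Feature",
                    "geometry": mapping(f.geometry),
                    "properties": f.properties,
                }
                for f in self.features
            ],
        }


class SchemaError(ValueError):
    """A layer or table lacks a required field."""


class CRSError(ValueError):
    """Input coordinates appear to be geographic (lon/lat) rather than planar."""


def _looks_geographic(geoms: Sequence[BaseGeometry]) -> bool:
    # Heuristic: every coordinate inside [-180,180]×[-90,90] over a non-empty
    # layer is overwhelmingly likely to be lon/lat; legitimate metric layers
    # at the scales this package targets span kilometers.
    if not geoms:
        return False
    xmin, ymin, xmax, ymax = shapely.total_bounds(list(geoms))
    if any(map(math.isnan, (xmin, ymin, xmax, ymax))):
        return False
    return -180.0 <= xmin <= xmax <= 180.0 and -90.0 <= ymin <= ymax <= 90.0


def read_geojson(path: str, require_planar: bool = True) -> FeatureLayer:
    """Read a FeatureCollection; reject apparent lon/lat input.

    Set ``require_planar=False`` only for layers that legitimately live in a
    small metric extent near the origin (e.g. unit-square test fixtures).
    """
    with open(path) as fh:
        doc = json.load(fh)
    return layer_from_geojson(doc, require_planar=require_planar)


def layer_from_geojson(doc: dict, require_planar: bool = True) -> FeatureLayer:
    if doc.get("type") != "FeatureCollection":
        raise SchemaError("expected a GeoJSON FeatureCollection")
    crs_name = str(doc.get("crs", {}).get("properties", {}).get("name", ""))
    if "4326" in crs_name or "CRS84" in crs_name:
        raise CRSError(
            "layer declares a geographic CRS; reproject to planar meters first"
        )
    feats = [
        Feature(shape(f["geometry"]), dict(f.get("properties") or {}))
        for f in doc["features"]
    ]
    if require_planar and _looks_geographic([f.geometry for f in feats]):
        raise CRSError(
            "coordinates fall inside lon/lat bounds; this looks like a "
            "geographic CRS — reproject to planar meters first"
        )
    return FeatureLayer(feats)


def write_geojson(layer: FeatureLayer, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(layer.to_geojson(), fh, indent=None, separators=(",", ":"))
        fh.write("\n")
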