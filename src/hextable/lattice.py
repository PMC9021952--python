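"""The point sampling frame: hexagonal lattice, centroid augmentation,
proximal (Voronoi) polygons, and geography keying.

The frame is a dense hexagonal lattice of sample points covering a
rectangular study extent; "spacing" is the nearest-neighbour
(center-to-center) distance, so rows sit ``spacing·√3/2`` apart vertically
and alternate rows are offset by half the spacing. Centroids of very small
polygons (census-block analogues) are merged into the lattice so that dense
urban geography is not under-sampled. Each point then receives a proximal
polygon — its Voronoi cell clipped to the extent — whose area lets point
tallies stand in for areal totals, and a set of geography keys (block,
tract, county, zip, …) that make tabular joins possible.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import MultiPoint, Point, box
from shapely.geometry.base import BaseGeometry
from shapely.strtree import STRtree

from .geojson import FeatureLayer, SchemaError
from .units import DEFAULT_AREA_THRESHOLD_M2, DEFAULT_SPACING_M

logger = logging.getLogger(__name__)

__all__ = [
    "Extent",
    "LatticeSpec",
    "PointTable",
    "generate_hex_lattice",
    "augment_with_centroids",
    "proximal_polygons",
    "assign_geography",
]

_EPS = 1e-9


class InvalidSpecError(ValueError):
    pass


class EmptyInputError(ValueError):
    pass


@dataclass(frozen=True)
class Extent:
    """Axis-aligned rectangular study extent in projected meters."""

    min_x: float
    min_y: float
    max_x: float
    max_y: float

    def __post_init__(self):
        vals = (self.min_x, self.min_y, self.max_x, self.max_y)
        if not all(math.isfinite(v) for v in vals):
            raise InvalidSpecError("extent coordinates must be finite")
        if not (self.max_x > self.min_x and self.max_y > self.min_y):
            raise InvalidSpecError("extent must have positive width and height")

    @property
    def width(self) -> float:
        return self.max_x - self.min_x

    @property
    def height(self) -> float:
        return self.max_y - self.min_y

    @property
    def area(self) -> float:
        return self.width * self.height

    def as_polygon(self):
        return box(self.min_x, self.min_y, self.max_x, self.max_y)

    def contains(self, x: float, y: float, tol: float = _EPS) -> bool:
        return (
            self.min_x - tol <= x <= self.max_x + tol
            and self.min_y - tol <= y <= self.max_y + tol
        )


@dataclass(frozen=True)
class LatticeSpec:
    """Lattice construction parameters.

    spacing_m
        Nearest-neighbour distance of the hex lattice, meters.
    area_threshold_m2
        Polygons strictly smaller than this get their centroid merged
        into the frame by :func:`augment_with_centroids`.
    """

    spacing_m: float = DEFAULT_SPACING_M
    area_threshold_m2: float = DEFAULT_AREA_THRESHOLD_M2

    def __post_init__(self):
        if not (self.spacing_m > 0 and math.isfinite(self.spacing_m)):
            raise InvalidSpecError("spacing_m must be positive and finite")
        if not (self.area_threshold_m2 > 0 and math.isfinite(self.area_threshold_m2)):
            raise InvalidSpecError("area_threshold_m2 must be positive and finite")


class PointTable:
    """The rows of the big table: one record per sample point.

    Backed by a DataFrame with columns ``point_id, x, y, origin_flag,
    proximal_area_m2`` plus one ``geo_<level>`` column per assigned
    geography level. Proximal polygon geometries are kept alongside after
    :func:`proximal_polygons` so surface attribution can clip against them.
    """

    GEO_PREFIX = "geo_"

    def __init__(self, df: pd.DataFrame, extent: Extent):
        required = {"point_id", "x", "y", "origin_flag", "proximal_area_m2"}
        missing = required - set(df.columns)
        if missing:
            raise SchemaError(f"PointTable missing columns: {sorted(missing)}")
        if df["point_id"].duplicated().any():
            raise ValueError("point_ids must be unique")
        self.df = df.reset_index(drop=True)
        self.extent = extent
        self.proximal_geoms: list[BaseGeometry] | None = None

    def __len__(self) -> int:
        return len(self.df)

    @property
    def point_ids(self) -> np.ndarray:
        return self.df["point_id"].to_numpy()

    @property
    def xy(self) -> np.ndarray:
        return self.df[["x", "y"]].to_numpy(dtype=float)

    @property
    def geography_levels(self) -> list[str]:
        p = self.GEO_PREFIX
        return [c[len(p):] for c in self.df.columns if c.startswith(p)]

    def geography_keys(self, level: str) -> pd.Series:
        col = self.GEO_PREFIX + level
        if col not in self.df.columns:
            raise KeyError(f"geography level {level!r} not assigned")
        return self.df[col]

    def copy(self) -> "PointTable":
        out = PointTable(self.df.copy(), self.extent)
        out.proximal_geoms = list(self.proximal_geoms) if self.proximal_geoms else None
        return out

    # -- persistence ------------------------------------------------------
    def to_csv(self, path: str) -> None:
        self.df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str, extent: Extent) -> "PointTable":
        df = pd.read_csv(path, dtype={"origin_flag": str})
        for c in df.columns:
            if c.startswith(cls.GEO_PREFIX):
                df[c] = df[c].astype("object").where(df[c].notna(), None)
                df[c] = df[c].map(lambda v: None if v is None else str(v))
        return cls(df, extent)

    def proximal_layer(self) -> FeatureLayer:
        if self.proximal_geoms is None:
            raise ValueError("proximal polygons not computed")
        from .geojson import Feature

        return FeatureLayer(
            Feature(g, {"point_id": int(pid)})
            for g, pid in zip(self.proximal_geoms, self.df["point_id"])
        )


def generate_hex_lattice(extent: Extent, spec: LatticeSpec) -> PointTable:
    """Lay a hexagonal point lattice over ``extent``.

    The origin point sits at ``(min_x, min_y)``; points on the extent
    boundary are kept. Deterministic: the construction is pure arithmetic.
    """
    s = spec.spacing_m
    dy = s * math.sqrt(3.0) / 2.0
    n_rows = int(math.floor(extent.height / dy + _EPS)) + 1
    xs: list[float] = []
    ys: list[float] = []
    for i in range(n_rows):
        y = extent.min_y + i * dy
        x0 = extent.min_x + (s / 2.0 if i % 2 else 0.0)
        n_cols = int(math.floor((extent.max_x - x0) / s + _EPS)) + 1
        if extent.max_x - x0 < -_EPS:
            continue
        for j in range(n_cols):
            xs.append(x0 + j * s)
            ys.append(y)
    df = pd.DataFrame(
        {
            "point_id": np.arange(len(xs), dtype=np.int64),
            "x": np.asarray(xs, dtype=float),
            "y": np.asarray(ys, dtype=float),
            "origin_flag": "lattice",
            "proximal_area_m2": np.nan,
        }
    )
    return PointTable(df, extent)


def augment_with_centroids(
    points: PointTable,
    polygons: FeatureLayer,
    area_threshold_m2: float | None = None,
) -> PointTable:
    """Append centroids of polygons with area strictly below the threshold.

    Invalid geometries are skipped with a logged warning; existing points
    and their ids are untouched, new ids continue the sequence.
    """
    thr = (
        area_threshold_m2
        if area_threshold_m2 is not None
        else DEFAULT_AREA_THRESHOLD_M2
    )
    next_id = int(points.df["point_id"].max()) + 1 if len(points) else 0
    rows = []
    for idx, feat in enumerate(polygons):
        geom = feat.geometry
        if geom.is_empty or not geom.is_valid:
            logger.warning("skipping invalid geometry at feature %d", idx)
            continue
        if geom.area < thr:
            c = geom.centroid
            rows.append((next_id, c.x, c.y, "centroid", np.nan))
            next_id += 1
    if not rows:
        return points.copy()
    add = pd.DataFrame(
        rows, columns=["point_id", "x", "y", "origin_flag", "proximal_area_m2"]
    )
    # carry over geography columns as nulls for the new points
    for col in points.df.columns:
        if col not in add.columns:
            add[col] = None
    df = pd.concat([points.df, add[points.df.columns]], ignore_index=True)
    out = PointTable(df, points.extent)
    return out


def proximal_polygons(points: PointTable, extent: Extent | None = None) -> PointTable:
    """Compute each point's proximal polygon (Voronoi cell clipped to the
    extent rectangle) and set ``proximal_area_m2``.

    Duplicate locations within 1e-9 m are collapsed onto the first id with
    a warning (the later duplicates get zero-area empty cells would be
    undefined; instead they share the survivor's cell and its area is
    assigned only to the survivor — duplicates receive area 0).
    """
    if extent is None:
        extent = points.extent
    n = len(points)
    if n == 0:
        raise EmptyInputError("proximal_polygons requires at least one point")
    xy = points.xy
    frame = extent.as_polygon()

    # collapse coincident sites (first id wins)
    key = np.round(xy / 1e-9).astype(np.int64)
    _, first_idx, inverse = np.unique(
        key, axis=0, return_index=True, return_inverse=True
    )
    if len(first_idx) < n:
        logger.warning(
            "collapsed %d duplicate point locations before Voronoi", n - len(first_idx)
        )
    survivor = first_idx[inverse]  # row index of each point's surviving site
    sites_idx = np.unique(survivor)
    sites = xy[sites_idx]

    geoms: list[BaseGeometry] = [None] * n  # type: ignore[list-item]
    areas = np.zeros(n, dtype=float)
    if len(sites) == 1:
        geoms[int(sites_idx[0])] = frame
        areas[int(sites_idx[0])] = frame.area
    else:
        mp = MultiPoint([Point(p) for p in sites])
        cells = shapely.voronoi_polygons(mp, extend_to=frame)
        clipped = [c.intersection(frame) for c in cells.geoms]
        tree = STRtree(clipped)
        for i, (sx, sy) in zip(sites_idx, sites):
            pt = Point(sx, sy)
            cell = None
            for ci in tree.query(pt, predicate="intersects"):
                if clipped[ci].covers(pt):
                    cell = clipped[ci]
                    break
            if cell is None:  # numerical edge: fall back to nearest cell
                cell = clipped[tree.nearest(pt)]
            geoms[int(i)] = cell
            areas[int(i)] = cell.area
    # duplicates share the survivor's geometry but contribute zero area
    for i in range(n):
        if geoms[i] is None:
            geoms[i] = geoms[int(survivor[i])]
    out = points.copy()
    out.df["proximal_area_m2"] = areas
    out.proximal_geoms = geoms
    total = areas.sum()
    if not math.isclose(total, extent.area, rel_tol=1e-6):
        logger.warning(
            "proximal areas sum %.6f differs from extent area %.6f", total, extent.area
        )
    return out


def assign_geography(
    points: PointTable,
    layer: FeatureLayer,
    level_name: str,
    code_field: str = "code",
) -> PointTable:
    """Key every point to the geography polygon containing it.

    Points outside all polygons get a null key (count logged). A point on a
    shared boundary goes to the containing polygon with the lowest feature
    index, which makes assignment order-stable and deterministic.
    """
    codes = layer.codes(code_field)
    geoms = layer.geometries
    tree = STRtree(geoms)
    pts = [Point(x, y) for x, y in points.xy]
    assigned: list[str | None] = [None] * len(pts)
    if pts:
        q = tree.query(pts, predicate="intersects")
        by_point: dict[int, list[int]] = {}
        for pi, gi in zip(q[0], q[1]):
            by_point.setdefault(int(pi), []).append(int(gi))
        for pi, cand in by_point.items():
            cand.sort()
            for gi in cand:
                if geoms[gi].covers(pts[pi]):
                    assigned[pi] = codes[gi]
                    break
    n_null = sum(a is None for a in assigned)
    if n_null:
        logger.info(
            "assign_geography(%s): %d/%d points outside all polygons",
            level_name, n_null, len(pts),
        )
    out = points.copy()
    out.df[PointTable.GEO_PREFIX + level_name] = pd.Series(assigned, dtype="object")
    return out
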