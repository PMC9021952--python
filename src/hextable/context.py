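"""Spatial context measures: distance to features, gridded density,
adjacency orders, network travel time, and aggregation to geographies.

Context here means quantified spatial relationships precomputed into plain
columns — a point's distance to the nearest park, the road length per km²
around it, which counties neighbour its county — so that later queries are
ordinary column predicates rather than on-the-fly GIS operations.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from shapely.geometry import Point, box
from shapely.strtree import STRtree

from .geojson import FeatureLayer
from .lattice import Extent, PointTable, assign_geography
from .units import M2_PER_KM2

logger = logging.getLogger(__name__)

__all__ = [
    "DensityGrid",
    "AdjacencyMap",
    "RoadNetwork",
    "distance_to_nearest",
    "density_grid",
    "adjacency_orders",
    "travel_time",
    "aggregate_by_geography",
]


class EmptyLayerError(ValueError):
    pass


@dataclass(frozen=True)
class DensityGrid:
    """Regular-grid density surface: cell value is a per-km² measure
    (feature count or line length in meters, divided by cell area)."""

    origin_x: float
    origin_y: float
    cell_size_m: float
    values: np.ndarray  # (n_rows, n_cols), row index grows with y

    def __post_init__(self):
        if self.cell_size_m <= 0:
            raise ValueError("cell_size_m must be positive")
        v = np.asarray(self.values, dtype=float)
        if (v < 0).any():
            raise ValueError("density values must be non-negative")
        object.__setattr__(self, "values", v)

    @property
    def cell_area_km2(self) -> float:
        return self.cell_size_m**2 / M2_PER_KM2

    def sample(self, x: float, y: float) -> float | None:
        i = int(math.floor((y - self.origin_y) / self.cell_size_m))
        j = int(math.floor((x - self.origin_x) / self.cell_size_m))
        n_i, n_j = self.values.shape
        if 0 <= i < n_i and 0 <= j < n_j:
            return float(self.values[i, j])
        return None

    def total(self) -> float:
        """Σ cell value × cell area — recovers the tallied quantity."""
        return float(self.values.sum() * self.cell_area_km2)


@dataclass
class AdjacencyMap:
    """First- and second-order contiguity neighbours per unit code."""

    first_order: dict[str, set[str]]
    second_order: dict[str, set[str]]

    @property
    def codes(self) -> list[str]:
        return sorted(self.first_order)

    def neighbors(self, code: str, order: str = "1") -> set[str]:
        if order == "1":
            return set(self.first_order[code])
        if order == "2":
            return set(self.second_order[code])
        if order in ("1+2", "12"):
            return self.first_order[code] | self.second_order[code]
        raise ValueError(f"unknown order {order!r}")

    def validate(self) -> None:
        for u, nbrs in self.first_order.items():
            if u in nbrs:
                raise ValueError(f"unit {u!r} is its own first-order neighbour")
            for v in nbrs:
                if u not in self.first_order.get(v, set()):
                    raise ValueError(f"asymmetric first-order pair ({u!r}, {v!r})")
        for u, nbrs in self.second_order.items():
            if u in nbrs:
                raise ValueError(f"unit {u!r} is its own second-order neighbour")
            if nbrs & self.first_order[u]:
                raise ValueError(f"unit {u!r}: first and second order overlap")


@dataclass
class RoadNetwork:
    """Undirected road graph with metric edge lengths and speeds."""

    nodes: pd.DataFrame  # columns: node_id, x, y
    edges: pd.DataFrame  # columns: u, v, length_m, speed_kmh

    def __post_init__(self):
        if (self.edges["length_m"] <= 0).any():
            raise ValueError("edge lengths must be positive")
        if (self.edges["speed_kmh"] <= 0).any():
            raise ValueError("edge speeds must be positive")

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        for r in self.nodes.itertuples(index=False):
            g.add_node(int(r.node_id), x=float(r.x), y=float(r.y))
        for r in self.edges.itertuples(index=False):
            minutes = (r.length_m / 1000.0) / r.speed_kmh * 60.0
            g.add_edge(int(r.u), int(r.v), length_m=float(r.length_m),
                       speed_kmh=float(r.speed_kmh), minutes=minutes)
        return g

    @property
    def max_speed_kmh(self) -> float:
        return float(self.edges["speed_kmh"].max())


def distance_to_nearest(points: PointTable, features: FeatureLayer) -> np.ndarray:
    """Planar Euclidean distance (m) from each point to the nearest feature."""
    if len(features) == 0:
        raise EmptyLayerError("feature layer is empty")
    tree = STRtree(features.geometries)
    pts = [Point(x, y) for x, y in points.xy]
    idx = tree.nearest(pts)
    geoms = features.geometries
    return np.array([pts[i].distance(geoms[j]) for i, j in enumerate(idx)])


def density_grid(
    features: FeatureLayer,
    extent: Extent,
    cell_size_m: float,
    measure: str = "point_count",
) -> DensityGrid:
    """Tally features into an artificial grid and express per km².

    ``point_count``: features per cell ÷ cell area. ``line_length``: length
    of line geometry clipped to each cell (m) ÷ cell area. Conservation
    holds by construction: Σ value·area = total count (or length inside the
    extent).
    """
    if cell_size_m <= 0:
        raise ValueError("cell_size_m must be positive")
    n_cols = int(math.ceil(extent.width / cell_size_m - 1e-9))
    n_rows = int(math.ceil(extent.height / cell_size_m - 1e-9))
    vals = np.zeros((n_rows, n_cols), dtype=float)
    cell_area = cell_size_m**2 / M2_PER_KM2
    if measure == "point_count":
        for f in features:
            g = f.geometry
            if g.geom_type != "Point":
                raise ValueError("point_count measure requires Point features")
            if not extent.contains(g.x, g.y, tol=0.0):
                continue
            i = min(int(math.floor((g.y - extent.min_y) / cell_size_m)), n_rows - 1)
            j = min(int(math.floor((g.x - extent.min_x) / cell_size_m)), n_cols - 1)
            vals[i, j] += 1.0
    elif measure == "line_length":
        for f in features:
            g = f.geometry
            if g.geom_type not in ("LineString", "MultiLineString"):
                raise ValueError("line_length measure requires line features")
            minx, miny, maxx, maxy = g.bounds
            j0 = max(0, int(math.floor((minx - extent.min_x) / cell_size_m)))
            j1 = min(n_cols - 1, int(math.floor((maxx - extent.min_x) / cell_size_m)))
            i0 = max(0, int(math.floor((miny - extent.min_y) / cell_size_m)))
            i1 = min(n_rows - 1, int(math.floor((maxy - extent.min_y) / cell_size_m)))
            for i in range(i0, i1 + 1):
                for j in range(j0, j1 + 1):
                    cell = box(
                        extent.min_x + j * cell_size_m,
                        extent.min_y + i * cell_size_m,
                        extent.min_x + (j + 1) * cell_size_m,
                        extent.min_y + (i + 1) * cell_size_m,
                    )
                    seg = g.intersection(cell)
                    if not seg.is_empty:
                        vals[i, j] += seg.length
    else:
        raise ValueError(f"unknown measure {measure!r}")
    vals /= cell_area
    return DensityGrid(extent.min_x, extent.min_y, cell_size_m, vals)


def attach_grid_values(points: PointTable, grid: DensityGrid) -> np.ndarray:
    """Per-point attribution: each point takes its containing cell's value."""
    out = np.full(len(points), np.nan)
    for k, (x, y) in enumerate(points.xy):
        v = grid.sample(x, y)
        if v is not None:
            out[k] = v
    return out


def adjacency_orders(
    layer: FeatureLayer,
    contiguity: str = "queen",
    code_field: str = "code",
) -> AdjacencyMap:
    """First- and second-order contiguity neighbours of polygon units.

    queen: any shared boundary point makes two units neighbours;
    rook: a shared boundary of positive length is required. Second order
    is neighbours-of-neighbours minus the unit and its first order.
    """
    if contiguity not in ("queen", "rook"):
        raise ValueError(f"unknown contiguity {contiguity!r}")
    codes = layer.codes(code_field)
    geoms = layer.geometries
    for i, g in enumerate(geoms):
        if not g.is_valid:
            raise ValueError(f"invalid geometry at feature {i} (code {codes[i]!r})")
    tree = STRtree(geoms)
    first: dict[str, set[str]] = {c: set() for c in codes}
    for i, g in enumerate(geoms):
        for j in tree.query(g, predicate="intersects"):
            j = int(j)
            if j == i:
                continue
            inter = g.intersection(geoms[j])
            if inter.is_empty:
                continue
            if contiguity == "rook" and inter.length <= 0:
                continue
            first[codes[i]].add(codes[j])
    second: dict[str, set[str]] = {}
    for c in codes:
        s: set[str] = set()
        for n in first[c]:
            s |= first[n]
        second[c] = s - first[c] - {c}
    amap = AdjacencyMap(first, second)
    amap.validate()
    return amap


def travel_time(
    points: PointTable,
    network: RoadNetwork | None,
    facilities: FeatureLayer,
    fallback_speed_kmh: float = 50.0,
) -> np.ndarray:
    """Minutes to the nearest facility via shortest network path.

    Each point (and each facility) is snapped to its nearest network node;
    the snap legs are charged as straight lines at the fallback speed, the
    path at edge speeds. Without a network, the straight-line time at the
    fallback speed is returned. Unreachable points get NaN with a warning.
    """
    if len(facilities) == 0:
        raise EmptyLayerError("no facilities given")
    fac_xy = np.array([[g.x, g.y] for g in facilities.geometries])
    pts_xy = points.xy
    if network is None or len(network.nodes) == 0:
        d = cKDTree(fac_xy).query(pts_xy)[0]
        return d / 1000.0 / fallback_speed_kmh * 60.0

    g = network.graph()
    node_ids = network.nodes["node_id"].to_numpy()
    node_xy = network.nodes[["x", "y"]].to_numpy(dtype=float)
    kdt = cKDTree(node_xy)

    fac_d, fac_i = kdt.query(fac_xy)
    fac_snap_min = fac_d / 1000.0 / fallback_speed_kmh * 60.0
    # multi-source Dijkstra with per-source offsets via a virtual node
    virt = "__facility__"
    g.add_node(virt)
    for d0, ni in zip(fac_snap_min, fac_i):
        nid = int(node_ids[ni])
        if not g.has_edge(virt, nid) or g[virt][nid]["minutes"] > d0:
            g.add_edge(virt, nid, minutes=float(d0))
    dist = nx.single_source_dijkstra_path_length(g, virt, weight="minutes")

    pt_d, pt_i = kdt.query(pts_xy)
    out = np.full(len(points), np.nan)
    for k in range(len(points)):
        nid = int(node_ids[pt_i[k]])
        if nid in dist:
            snap_min = pt_d[k] / 1000.0 / fallback_speed_kmh * 60.0
            out[k] = snap_min + dist[nid]
    n_unreach = int(np.isnan(out).sum())
    if n_unreach:
        logger.warning("travel_time: %d points unreachable", n_unreach)
    return out


def aggregate_by_geography(
    points: PointTable,
    values: pd.Series | np.ndarray,
    layer: FeatureLayer | None = None,
    level: str | None = None,
    stat: str = "mean",
    code_field: str = "code",
) -> pd.Series:
    """Summarise a per-point attribute to geography units.

    Pass either an already-assigned ``level`` or a polygon ``layer`` to key
    against on the fly (the "user-defined geography" case). The statistic
    is unweighted over non-null member points; empty units come back null.
    """
    stats = {"mean", "sum", "min", "max", "count"}
    if stat not in stats:
        raise ValueError(f"unknown stat {stat!r}; choose from {sorted(stats)}")
    if (layer is None) == (level is None):
        raise ValueError("pass exactly one of layer= or level=")
    if layer is not None:
        level = "_adhoc"
        points = assign_geography(points, layer, level, code_field)
        all_codes = layer.codes(code_field)
    else:
        all_codes = sorted(
            {k for k in points.geography_keys(level) if k is not None}
        )
    keys = points.geography_keys(level)
    vals = pd.to_numeric(pd.Series(np.asarray(values, dtype=object)), errors="coerce")
    df = pd.DataFrame({"key": keys.to_numpy(), "v": vals.to_numpy(dtype=float)})
    df = df[df["key"].notna() & df["v"].notna()]
    grouped = df.groupby("key")["v"]
    agg = {
        "mean": grouped.mean,
        "sum": grouped.sum,
        "min": grouped.min,
        "max": grouped.max,
        "count": grouped.count,
    }[stat]()
    out = pd.Series(np.nan, index=pd.Index(sorted(set(all_codes)), name="code"))
    out.loc[agg.index] = agg.to_numpy(dtype=float)
    n_empty = int(out.isna().sum())
    if n_empty:
        logger.warning("aggregate_by_geography: %d units with no points", n_empty)
    return out
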