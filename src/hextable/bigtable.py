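"""The location-keyed big table and its provenance catalog.

One row per sample point, one column per attribute; every column carries a
metadata record tied to a registered source, so any extract can be shipped
with a complete source report. Values are null-aware throughout: a point a
dataset does not cover stays null, never zero.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from typing import Any, Iterable, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import Point
from shapely.strtree import STRtree

from .geojson import FeatureLayer, SchemaError
from .lattice import PointTable
from .units import M2_PER_KM2

logger = logging.getLogger(__name__)

__all__ = [
    "ISO_19115_CATEGORIES",
    "ATTRIBUTE_KINDS",
    "SourceRecord",
    "AttributeMetadata",
    "SurfaceGrid",
    "BigTable",
    "ExtractReport",
    "CatalogError",
    "IngestionError",
]

#: The 19 thematic category names of the ISO 19115 metadata standard.
ISO_19115_CATEGORIES = frozenset(
    {
        "farming",
        "biota",
        "boundaries",
        "climatologyMeteorologyAtmosphere",
        "economy",
        "elevation",
        "environment",
        "geoscientificInformation",
        "health",
        "imageryBaseMapsEarthCover",
        "intelligenceMilitary",
        "inlandWaters",
        "location",
        "oceans",
        "planningCadastre",
        "society",
        "structure",
        "transportation",
        "utilitiesCommunication",
    }
)

ATTRIBUTE_KINDS = frozenset(
    {"count", "density", "rate", "categorical", "distance_m", "time_min", "score", "other"}
)


class CatalogError(ValueError):
    pass


class IngestionError(ValueError):
    pass


@dataclass(frozen=True)
class SourceRecord:
    source_id: str
    name: str
    url: str = ""
    use_constraints: str = ""
    retrieved_date: str = ""
    description: str = ""

    def __post_init__(self):
        if not self.source_id or not self.name:
            raise CatalogError("source_id and name are required")


@dataclass(frozen=True)
class AttributeMetadata:
    attr_id: str
    source_id: str
    native_level: str = "point"
    vintage: str = ""
    iso_category: str = "location"
    tags: tuple[str, ...] = ()
    units: str = ""
    kind: str = "other"

    def __post_init__(self):
        if not self.attr_id:
            raise CatalogError("attr_id is required")
        if self.iso_category not in ISO_19115_CATEGORIES:
            raise CatalogError(
                f"unknown ISO 19115 category {self.iso_category!r}"
            )
        if self.kind not in ATTRIBUTE_KINDS:
            raise CatalogError(f"unknown attribute kind {self.kind!r}")
        object.__setattr__(self, "tags", tuple(self.tags))


@dataclass(frozen=True)
class SurfaceGrid:
    """Axis-aligned regular grid surface: ``values[i, j]`` covers the cell
    with lower-left corner ``(origin_x + j·cell, origin_y + i·cell)``."""

    origin_x: float
    origin_y: float
    cell_size_m: float
    values: np.ndarray  # 2-D, row index grows with y

    def __post_init__(self):
        if self.cell_size_m <= 0:
            raise ValueError("cell_size_m must be positive")
        object.__setattr__(self, "values", np.asarray(self.values))

    def cell_of(self, x: float, y: float) -> tuple[int, int] | None:
        i = int(np.floor((y - self.origin_y) / self.cell_size_m))
        j = int(np.floor((x - self.origin_x) / self.cell_size_m))
        n_i, n_j = self.values.shape
        if 0 <= i < n_i and 0 <= j < n_j:
            return i, j
        return None

    def sample(self, x: float, y: float):
        ij = self.cell_of(x, y)
        return None if ij is None else self.values[ij]


@dataclass
class ExtractReport:
    selection_description: str
    row_count: int
    attributes: list[AttributeMetadata]
    sources: list[SourceRecord]

    def to_json(self) -> str:
        doc = {
            "selection_description": self.selection_description,
            "row_count": self.row_count,
            "attributes": [asdict(a) for a in self.attributes],
            "sources": [asdict(s) for s in self.sources],
        }
        return json.dumps(doc, indent=2, sort_keys=True)


class BigTable:
    """Point × attribute matrix with an enforced provenance catalog.

    Every data column must be registered (:meth:`register_attribute`)
    against an existing source before values may be attached; the converse
    orphan (metadata without a column) is allowed only transiently, since
    registration necessarily precedes ingestion.
    """

    def __init__(self, points: PointTable):
        self.points = points
        self.data = pd.DataFrame(index=pd.Index(points.point_ids, name="point_id"))
        self.sources: dict[str, SourceRecord] = {}
        self.attributes: dict[str, AttributeMetadata] = {}

    # -- catalog ----------------------------------------------------------
    def register_source(self, record: SourceRecord) -> str:
        existing = self.sources.get(record.source_id)
        if existing is not None:
            if existing != record:
                raise CatalogError(
                    f"source {record.source_id!r} already registered with "
                    "different content"
                )
            return record.source_id  # idempotent
        self.sources[record.source_id] = record
        return record.source_id

    def register_attribute(self, meta: AttributeMetadata) -> str:
        if meta.source_id not in self.sources:
            raise CatalogError(f"unknown source {meta.source_id!r}")
        if meta.attr_id in self.attributes:
            raise CatalogError(f"attribute {meta.attr_id!r} already registered")
        self.attributes[meta.attr_id] = meta
        return meta.attr_id

    def search_metadata(
        self,
        terms: Sequence[str],
        fields: Iterable[str] = ("name", "tags", "iso_category", "source"),
    ) -> list[str]:
        """Case-insensitive substring search; multiple terms take union
        semantics. An empty term list matches everything."""
        fields = set(fields)
        unknown = fields - {"name", "tags", "iso_category", "source"}
        if unknown:
            raise ValueError(f"unknown search fields: {sorted(unknown)}")
        terms_l = [t.lower() for t in terms]
        hits = []
        for attr_id, meta in self.attributes.items():
            hay: list[str] = []
            if "name" in fields:
                hay.append(attr_id.lower())
            if "tags" in fields:
                hay.extend(t.lower() for t in meta.tags)
            if "iso_category" in fields:
                hay.append(meta.iso_category.lower())
            if "source" in fields:
                src = self.sources[meta.source_id]
                hay.extend([src.source_id.lower(), src.name.lower()])
            if not terms_l or any(t in h for t in terms_l for h in hay):
                hits.append(attr_id)
        return sorted(hits)

    def _require_attr(self, attr_id: str) -> AttributeMetadata:
        try:
            return self.attributes[attr_id]
        except KeyError:
            raise CatalogError(f"unknown attribute {attr_id!r}") from None

    def _attach_column(self, attr_id: str, values: pd.Series) -> None:
        self._require_attr(attr_id)
        if len(values) != len(self.points):
            raise IngestionError(
                f"column {attr_id!r} length {len(values)} != {len(self.points)} points"
            )
        self.data[attr_id] = values.to_numpy()

    def column(self, attr_id: str) -> pd.Series:
        self._require_attr(attr_id)
        if attr_id not in self.data.columns:
            raise CatalogError(f"attribute {attr_id!r} registered but not loaded")
        return self.data[attr_id]

    # -- ingestion --------------------------------------------------------
    def join_tabular(
        self, table: pd.DataFrame, key_column: str, key_level: str,
        attr_ids: Sequence[str] | None = None,
    ) -> None:
        """Attach columns of a geography-keyed table to every point via its
        geography key. Unmatched or null-keyed points stay null."""
        if table[key_column].duplicated().any():
            dup = table[key_column][table[key_column].duplicated()].iloc[0]
            raise IngestionError(f"duplicate key {dup!r} in input table")
        keys = self.points.geography_keys(key_level).astype("object")
        lookup = table.set_index(table[key_column].astype(str))
        cols = list(attr_ids) if attr_ids is not None else [
            c for c in table.columns if c != key_column
        ]
        for c in cols:
            self._require_attr(c)
        matched = keys.map(lambda k: k is not None and str(k) in lookup.index)
        logger.info(
            "join_tabular(%s): %d/%d points matched", key_level,
            int(matched.sum()), len(keys),
        )
        for c in cols:
            colmap = lookup[c].to_dict()
            vals = keys.map(lambda k: colmap.get(str(k)) if k is not None else None)
            self._attach_column(c, vals)

    def attribute_from_features(
        self,
        attr_id: str,
        layer: FeatureLayer | SurfaceGrid,
        mode: str,
        value_field: str | None = None,
    ) -> None:
        """Attach an attribute derived from a spatial layer.

        modes: ``polygon_value`` (point-in-polygon field transfer),
        ``distance`` (meters to nearest feature), ``surface_sample`` (grid
        value at the point), ``surface_majority`` (area-weighted modal grid
        value over the point's proximal polygon).
        """
        self._require_attr(attr_id)
        if mode == "polygon_value":
            if not isinstance(layer, FeatureLayer):
                raise IngestionError("polygon_value mode needs a polygon layer")
            if value_field is None:
                raise IngestionError("polygon_value mode needs value_field")
            vals = _polygon_value(self.points, layer, value_field)
        elif mode == "distance":
            if not isinstance(layer, FeatureLayer):
                raise IngestionError("distance mode needs a feature layer")
            from .context import distance_to_nearest

            vals = pd.Series(distance_to_nearest(self.points, layer))
        elif mode == "surface_sample":
            if not isinstance(layer, SurfaceGrid):
                raise IngestionError("surface_sample mode needs a SurfaceGrid")
            vals = pd.Series(
                [layer.sample(x, y) for x, y in self.points.xy], dtype="object"
            )
        elif mode == "surface_majority":
            if not isinstance(layer, SurfaceGrid):
                raise IngestionError("surface_majority mode needs a SurfaceGrid")
            vals = _surface_majority(self.points, layer)
        else:
            raise IngestionError(f"unknown mode {mode!r}")
        self._attach_column(attr_id, pd.Series(vals).reset_index(drop=True))

    # -- density / estimation --------------------------------------------
    def to_density(
        self, count_attr: str, level: str, density_attr: str | None = None
    ) -> str:
        """Convert a count attribute at a geography level to per-km² density.

        The unit's area is the sum of its member points' proximal areas, so
        tallying density × proximal area over the unit recovers the count
        exactly. The density column is auto-registered (kind=density).
        """
        meta = self._require_attr(count_attr)
        if meta.kind != "count":
            raise IngestionError(f"{count_attr!r} has kind {meta.kind!r}, not count")
        if meta.native_level != level:
            raise IngestionError(
                f"{count_attr!r} native level is {meta.native_level!r}, not {level!r}"
            )
        areas = self.points.df["proximal_area_m2"]
        if areas.isna().any():
            raise IngestionError("proximal areas not computed")
        name = density_attr or f"{count_attr}_per_km2"
        keys = self.points.geography_keys(level)
        counts = self.column(count_attr)
        area_km2 = areas.to_numpy() / M2_PER_KM2
        unit_area = pd.Series(area_km2).groupby(keys.to_numpy()).sum()
        dens = np.full(len(self.points), np.nan)
        for u, a in unit_area.items():
            mask = (keys == u).to_numpy()
            cvals = pd.to_numeric(counts[mask], errors="coerce")
            c = cvals.dropna().iloc[0] if cvals.notna().any() else None
            if c is None:
                continue
            if a <= 0:
                logger.warning("unit %r has zero summed proximal area", u)
                continue
            dens[mask] = float(c) / a
        if name not in self.attributes:
            self.register_attribute(
                AttributeMetadata(
                    attr_id=name,
                    source_id=meta.source_id,
                    native_level=level,
                    vintage=meta.vintage,
                    iso_category=meta.iso_category,
                    tags=meta.tags + ("density",),
                    units="per km2",
                    kind="density",
                )
            )
        self._attach_column(name, pd.Series(dens))
        return name

    def estimate_total(
        self, selection: Sequence[int], density_attr: str
    ) -> tuple[float, float]:
        """Estimate a count over a point selection as Σ density·proximal area.

        Returns ``(estimate, coverage)`` where coverage is the fraction of
        the selection's proximal area carrying non-null density.
        """
        meta = self._require_attr(density_attr)
        if meta.kind != "density":
            raise IngestionError(f"{density_attr!r} is not a density attribute")
        sel = np.asarray(sorted(set(int(s) for s in selection)), dtype=np.int64)
        if sel.size == 0:
            return 0.0, 1.0
        sub = self.data.loc[sel, density_attr].to_numpy(dtype=float)
        areas = (
            self.points.df.set_index("point_id")
            .loc[sel, "proximal_area_m2"]
            .to_numpy(dtype=float)
            / M2_PER_KM2
        )
        ok = ~np.isnan(sub)
        total_area = areas.sum()
        coverage = float(areas[ok].sum() / total_area) if total_area > 0 else 1.0
        if not ok.all():
            logger.warning(
                "estimate_total: %d/%d selected points have null density "
                "(area coverage %.3f)", int((~ok).sum()), sel.size, coverage,
            )
        return float(np.nansum(sub[ok] * areas[ok])), coverage

    # -- extraction -------------------------------------------------------
    def extract(
        self,
        selection: Sequence[int] | None,
        attr_ids: Sequence[str],
        description: str = "",
    ) -> tuple[pd.DataFrame, ExtractReport]:
        """Flat analysis-ready table + source report for the selection."""
        metas = [self._require_attr(a) for a in attr_ids]
        pts = self.points.df.set_index("point_id")
        ids = (
            np.asarray(sorted(set(int(s) for s in selection)), dtype=np.int64)
            if selection is not None
            else np.sort(self.points.point_ids)
        )
        out = pd.DataFrame(
            {
                "point_id": ids,
                "x": pts.loc[ids, "x"].to_numpy(),
                "y": pts.loc[ids, "y"].to_numpy(),
            }
        )
        for a in attr_ids:
            out[a] = self.column(a).loc[ids].to_numpy()
        src_ids = sorted({m.source_id for m in metas})
        report = ExtractReport(
            selection_description=description,
            row_count=len(out),
            attributes=metas,
            sources=[self.sources[s] for s in src_ids],
        )
        return out, report


def _polygon_value(points: PointTable, layer: FeatureLayer, value_field: str):
    geoms = layer.geometries
    try:
        values = [f.properties[value_field] for f in layer]
    except KeyError as exc:
        raise SchemaError(f"features missing field {value_field!r}") from exc
    tree = STRtree(geoms)
    pts = [Point(x, y) for x, y in points.xy]
    out: list[Any] = [None] * len(pts)
    if pts:
        q = tree.query(pts, predicate="intersects")
        by_point: dict[int, list[int]] = {}
        for pi, gi in zip(q[0], q[1]):
            by_point.setdefault(int(pi), []).append(int(gi))
        for pi, cand in by_point.items():
            for gi in sorted(cand):
                if geoms[gi].covers(pts[pi]):
                    out[pi] = values[gi]
                    break
    return pd.Series(out, dtype="object")


def _surface_majority(points: PointTable, grid: SurfaceGrid) -> pd.Series:
    """Area-weighted modal grid value over each point's proximal polygon."""
    from shapely.geometry import box as _box

    if points.proximal_geoms is None:
        raise IngestionError("surface_majority requires proximal polygons")
    cs = grid.cell_size_m
    n_i, n_j = grid.values.shape
    out: list[Any] = []
    for poly in points.proximal_geoms:
        minx, miny, maxx, maxy = poly.bounds
        j0 = max(0, int(np.floor((minx - grid.origin_x) / cs)))
        j1 = min(n_j - 1, int(np.floor((maxx - grid.origin_x) / cs)))
        i0 = max(0, int(np.floor((miny - grid.origin_y) / cs)))
        i1 = min(n_i - 1, int(np.floor((maxy - grid.origin_y) / cs)))
        weights: dict[Any, float] = {}
        for i in range(i0, i1 + 1):
            for j in range(j0, j1 + 1):
                cell = _box(
                    grid.origin_x + j * cs,
                    grid.origin_y + i * cs,
                    grid.origin_x + (j + 1) * cs,
                    grid.origin_y + (i + 1) * cs,
                )
                a = poly.intersection(cell).area
                if a > 0:
                    v = grid.values[i, j]
                    weights[v] = weights.get(v, 0.0) + a
        if weights:
            # deterministic tie-break: largest area, then smallest value repr
            out.append(sorted(weights.items(), key=lambda kv: (-kv[1], str(kv[0])))[0][0])
        else:
            out.append(None)
    return pd.Series(out, dtype="object")


def table_hash(df: pd.DataFrame) -> str:
    """Stable content hash of a DataFrame, for byte-reproducibility checks."""
    csv = df.to_csv(index=False).encode()
    return hashlib.sha256(csv).hexdigest()
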