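"""Manifest-driven pipeline orchestration.

Each stage reads its inputs from files in a working directory and writes
its outputs there, so the chain

    fixtures → lattice → ingest → context → query → score

runs end to end from a single manifest and a seed, with every output
written atomically (temp file, then rename) and byte-reproducible for a
fixed seed. The CLI is a thin wrapper over these functions; they are
equally usable directly from Python.
"""

from __future__ import annotations

import json
import os
import tempfile
from dataclasses import asdict
from typing import Any, Callable

import numpy as np
import pandas as pd
import yaml

from . import context as ctx
from .bigtable import AttributeMetadata, BigTable, SourceRecord, table_hash
from .fixtures import (
    make_autocorrelated_field,
    make_feature_layers,
    make_grid_geography,
    roads_as_layer,
)
from .geojson import FeatureLayer, read_geojson, write_geojson
from .health_scores import risk_table
from .lattice import (
    Extent,
    LatticeSpec,
    PointTable,
    assign_geography,
    augment_with_centroids,
    generate_hex_lattice,
    proximal_polygons,
)
from .query import evaluate, parse_query
from .spatial_stats import build_weights, local_moran, skater_cluster

__all__ = ["Manifest", "ManifestError", "load_manifest", "run_stage", "STAGES"]


class ManifestError(ValueError):
    """Manifest schema violation, reported with a /path/to/field pointer."""


def _req(doc: dict, path: str, typ=None):
    cur: Any = doc
    walked = ""
    for part in path.strip("/").split("/"):
        walked += "/" + part
        if not isinstance(cur, dict) or part not in cur:
            raise ManifestError(f"missing required field {walked}")
        cur = cur[part]
    if typ is not None and not isinstance(cur, typ):
        raise ManifestError(f"field {walked} has wrong type (expected {typ})")
    return cur


class Manifest:
    def __init__(self, doc: dict):
        if not isinstance(doc, dict):
            raise ManifestError("manifest root must be a mapping")
        self.doc = doc
        e = _req(doc, "/extent", dict)
        self.extent = Extent(
            float(_req(doc, "/extent/min_x")),
            float(_req(doc, "/extent/min_y")),
            float(_req(doc, "/extent/max_x")),
            float(_req(doc, "/extent/max_y")),
        )
        lat = doc.get("lattice", {})
        self.lattice_spec = LatticeSpec(
            spacing_m=float(lat.get("spacing_m", 161.0)),
            area_threshold_m2=float(lat.get("area_threshold_m2", 67261.0)),
        )
        self.seed = int(doc.get("seed", 0))

    def get(self, key: str, default=None):
        return self.doc.get(key, default)


def load_manifest(path: str) -> Manifest:
    with open(path) as fh:
        doc = yaml.safe_load(fh) if path.endswith((".yml", ".yaml")) else json.load(fh)
    return Manifest(doc)


def _atomic_write(path: str, writer: Callable[[str], None]) -> None:
    d = os.path.dirname(os.path.abspath(path)) or "."
    os.makedirs(d, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=d, suffix=".tmp")
    os.close(fd)
    try:
        writer(tmp)
        os.replace(tmp, path)
    finally:
        if os.path.exists(tmp):
            os.unlink(tmp)


def _write_csv(df: pd.DataFrame, path: str) -> None:
    _atomic_write(path, lambda p: df.to_csv(p, index=False))


def _write_json(doc: Any, path: str) -> None:
    _atomic_write(
        path, lambda p: open(p, "w").write(json.dumps(doc, indent=2, sort_keys=True))
    )


# ---------------------------------------------------------------------------
# stages


def stage_fixtures(manifest: Manifest, out_dir: str) -> dict:
    """Generate toy geography, feature layers, and county attributes."""
    fx = manifest.get("fixtures", {})
    geo = make_grid_geography(
        int(fx.get("n_rows", 6)), int(fx.get("n_cols", 6)),
        float(fx.get("cell_km", 1.0)), int(fx.get("blocks_per_county", 4)),
    )
    parks, hospitals, roads = make_feature_layers(
        geo, manifest.seed,
        n_parks=int(fx.get("n_parks", 12)),
        n_hospitals=int(fx.get("n_hospitals", 4)),
    )
    for name, layer in [
        ("blocks", geo.blocks), ("tracts", geo.tracts),
        ("counties", geo.counties), ("state", geo.state),
        ("parks", parks), ("hospitals", hospitals),
        ("roads", roads_as_layer(roads)),
    ]:
        _atomic_write(
            os.path.join(out_dir, f"{name}.geojson"),
            lambda p, la=layer: write_geojson(la, p),
        )
    adj = ctx.adjacency_orders(geo.counties)
    field = make_autocorrelated_field(adj, float(fx.get("rho", 0.5)), manifest.seed)
    rng = np.random.default_rng(manifest.seed + 1)
    codes = geo.counties.codes()
    pop = rng.integers(500, 5000, size=len(codes))
    tab = pd.DataFrame(
        {"code": codes, "population": pop,
         "risk_field": field.loc[codes].round(9).to_numpy()}
    )
    _write_csv(tab, os.path.join(out_dir, "county_attributes.csv"))
    return {"counties": len(codes), "parks": len(parks), "hospitals": len(hospitals)}


def stage_lattice(manifest: Manifest, out_dir: str) -> dict:
    """Hex lattice + centroid augmentation + proximal areas + geography keys."""
    pt = generate_hex_lattice(manifest.extent, manifest.lattice_spec)
    blocks_path = os.path.join(out_dir, "blocks.geojson")
    if os.path.exists(blocks_path):
        blocks = read_geojson(blocks_path)
        pt = augment_with_centroids(pt, blocks, manifest.lattice_spec.area_threshold_m2)
    pt = proximal_polygons(pt)
    for level in ("county", "tract"):
        path = os.path.join(out_dir, f"{'counties' if level == 'county' else 'tracts'}.geojson")
        if os.path.exists(path):
            pt = assign_geography(pt, read_geojson(path), level)
    _atomic_write(os.path.join(out_dir, "points.csv"), pt.to_csv)
    _atomic_write(
        os.path.join(out_dir, "proximal.geojson"),
        lambda p: write_geojson(pt.proximal_layer(), p),
    )
    return {"points": len(pt)}


def _load_points(manifest: Manifest, out_dir: str) -> PointTable:
    pt = PointTable.from_csv(os.path.join(out_dir, "points.csv"), manifest.extent)
    prox = os.path.join(out_dir, "proximal.geojson")
    if os.path.exists(prox):
        layer = read_geojson(prox)
        order = {int(f.properties["point_id"]): f.geometry for f in layer}
        pt.proximal_geoms = [order[int(pid)] for pid in pt.point_ids]
    return pt


def _save_bigtable(bt: BigTable, out_dir: str) -> None:
    df = bt.data.reset_index()
    _write_csv(df, os.path.join(out_dir, "bigtable.csv"))
    catalog = {
        "sources": {k: asdict(v) for k, v in sorted(bt.sources.items())},
        "attributes": {k: asdict(v) for k, v in sorted(bt.attributes.items())},
    }
    _write_json(catalog, os.path.join(out_dir, "catalog.json"))


def _load_bigtable(manifest: Manifest, out_dir: str) -> BigTable:
    pt = _load_points(manifest, out_dir)
    bt = BigTable(pt)
    cat_path = os.path.join(out_dir, "catalog.json")
    data_path = os.path.join(out_dir, "bigtable.csv")
    if os.path.exists(cat_path):
        with open(cat_path) as fh:
            cat = json.load(fh)
        for rec in cat["sources"].values():
            bt.register_source(SourceRecord(**rec))
        for rec in cat["attributes"].values():
            rec = dict(rec)
            rec["tags"] = tuple(rec.get("tags", ()))
            bt.register_attribute(AttributeMetadata(**rec))
    if os.path.exists(data_path):
        df = pd.read_csv(data_path).set_index("point_id")
        for c in df.columns:
            bt.data[c] = df[c].reindex(bt.data.index).to_numpy()
    return bt


def stage_ingest(manifest: Manifest, out_dir: str) -> dict:
    """Register sources/attributes and join tabular county data."""
    bt = _load_bigtable(manifest, out_dir)
    for s in manifest.get("sources", []):
        bt.register_source(SourceRecord(**s))
    for a in manifest.get("attributes", []):
        a = dict(a)
        table_file = a.pop("file", None)
        key_column = a.pop("key_column", "code")
        key_level = a.pop("key_level", a.get("native_level", "county"))
        a["tags"] = tuple(a.get("tags", ()))
        meta = AttributeMetadata(**a)
        if meta.attr_id not in bt.attributes:
            bt.register_attribute(meta)
        if table_file:
            tab = pd.read_csv(os.path.join(out_dir, table_file))
            bt.join_tabular(tab, key_column, key_level, attr_ids=[meta.attr_id])
    for d in manifest.get("densities", []):
        bt.to_density(_req(d, "/count_attr"), _req(d, "/level"))
    _save_bigtable(bt, out_dir)
    return {"attributes": len(bt.attributes), "points": len(bt.points)}


def stage_context(manifest: Manifest, out_dir: str) -> dict:
    """Precompute context-measure columns named in the manifest."""
    bt = _load_bigtable(manifest, out_dir)
    added = []
    for spec in manifest.get("context", []):
        attr = _req(spec, "/attr_id")
        mode = _req(spec, "/mode")
        src = spec.get("source_id", "derived")
        if src not in bt.sources:
            bt.register_source(SourceRecord(src, name="derived context measures"))
        if attr not in bt.attributes:
            bt.register_attribute(
                AttributeMetadata(
                    attr_id=attr, source_id=src,
                    iso_category=spec.get("iso_category", "location"),
                    kind=spec.get("kind", "other"),
                    tags=tuple(spec.get("tags", ())), units=spec.get("units", ""),
                )
            )
        if mode == "distance":
            layer = read_geojson(os.path.join(out_dir, _req(spec, "/file")))
            vals = ctx.distance_to_nearest(bt.points, layer)
        elif mode == "density_grid":
            layer = read_geojson(os.path.join(out_dir, _req(spec, "/file")))
            grid = ctx.density_grid(
                layer, manifest.extent, float(_req(spec, "/cell_size_m")),
                measure=spec.get("measure", "point_count"),
            )
            vals = ctx.attach_grid_values(bt.points, grid)
        elif mode == "travel_time":
            fac = read_geojson(os.path.join(out_dir, _req(spec, "/facilities")))
            net = None
            if spec.get("network"):
                net = _road_network_from_layer(
                    read_geojson(os.path.join(out_dir, spec["network"]))
                )
            vals = ctx.travel_time(
                bt.points, net, fac,
                fallback_speed_kmh=float(spec.get("fallback_speed_kmh", 50.0)),
            )
        else:
            raise ManifestError(f"unknown context mode {mode!r}")
        bt.data[attr] = np.round(np.asarray(vals, dtype=float), 9)
        added.append(attr)
    _save_bigtable(bt, out_dir)
    return {"context_attributes": added}


def _road_network_from_layer(layer: FeatureLayer) -> ctx.RoadNetwork:
    """Build a node/edge network from a LineString layer; node identity is
    coordinate-based, lengths recomputed from geometry when absent."""
    nodes: dict[tuple[float, float], int] = {}
    erows = []

    def nid(xy):
        key = (round(xy[0], 6), round(xy[1], 6))
        if key not in nodes:
            nodes[key] = len(nodes)
        return nodes[key]

    for f in layer:
        g = f.geometry
        coords = list(g.coords)
        for a, b in zip(coords[:-1], coords[1:]):
            length = f.properties.get("length_m") or float(
                np.hypot(b[0] - a[0], b[1] - a[1])
            )
            speed = float(f.properties.get("speed_kmh", 50.0))
            erows.append((nid(a), nid(b), float(length), speed))
    ndf = pd.DataFrame(
        [(i, x, y) for (x, y), i in nodes.items()], columns=["node_id", "x", "y"]
    ).sort_values("node_id").reset_index(drop=True)
    edf = pd.DataFrame(erows, columns=["u", "v", "length_m", "speed_kmh"])
    return ctx.RoadNetwork(ndf, edf)


def stage_query(manifest: Manifest, out_dir: str) -> dict:
    bt = _load_bigtable(manifest, out_dir)
    q = manifest.get("query", {})
    expr = parse_query(q.get("expression", ""))
    sel = evaluate(bt, expr)
    _write_csv(pd.DataFrame({"point_id": sel.point_ids}),
               os.path.join(out_dir, "selection.csv"))
    attrs = q.get("attrs", [])
    if attrs:
        table, report = bt.extract(sel.point_ids, attrs, description=sel.provenance)
        _write_csv(table, os.path.join(out_dir, "extract.csv"))
        _atomic_write(
            os.path.join(out_dir, "extract_report.json"),
            lambda p: open(p, "w").write(report.to_json()),
        )
    return {"selected": len(sel), "expression": sel.provenance}


def stage_score(manifest: Manifest, out_dir: str) -> dict:
    """County risk scores → LISA on the composite → SKATER regions."""
    bt = _load_bigtable(manifest, out_dir)
    sc = manifest.get("scores", {})
    level = sc.get("level", "county")
    counties = read_geojson(os.path.join(out_dir, "counties.geojson"))
    adj = ctx.adjacency_orders(counties)
    codes = sorted(adj.first_order)

    cat_cfg: dict[str, list[tuple[str, bool]]] = {}
    for cat, vars_ in sc.get(
        "categories", {"risk": [{"attr": "risk_field", "worse_is_high": True}]}
    ).items():
        cat_cfg[cat] = [
            (v["attr"], bool(v.get("worse_is_high", True))) for v in vars_
        ]
    unit_data = pd.DataFrame(index=range(len(codes)))
    for cat, specs in cat_cfg.items():
        for attr, _wh in specs:
            agg = ctx.aggregate_by_geography(
                bt.points, bt.column(attr).to_numpy(), level=level, stat="mean"
            )
            unit_data[attr] = agg.reindex(codes).to_numpy()
    rt = risk_table(codes, unit_data, cat_cfg)

    w = build_weights(adj, standardize="row")
    lisa = local_moran(
        rt.composite, w, n_perm=int(sc.get("n_perm", 999)), seed=manifest.seed
    )
    k = int(sc.get("k_regions", 4))
    clusters = skater_cluster(codes, unit_data.to_numpy(dtype=float), adj, k)

    out = rt.to_frame()
    out["lisa_i"] = np.round(lisa.local_i, 9)
    out["lisa_p"] = lisa.pseudo_p
    out["lisa_label"] = lisa.labels
    out["region"] = clusters.labels
    num_cols = out.select_dtypes(include=[float]).columns
    out[num_cols] = out[num_cols].round(9)
    _write_csv(out, os.path.join(out_dir, "scores.csv"))
    return {"units": len(codes), "k_regions": clusters.k,
            "scores_hash": table_hash(out)}


STAGES: dict[str, Callable[[Manifest, str], dict]] = {
    "fixtures": stage_fixtures,
    "lattice": stage_lattice,
    "ingest": stage_ingest,
    "context": stage_context,
    "query": stage_query,
    "score": stage_score,
}


def run_stage(name: str, manifest: Manifest, out_dir: str) -> dict:
    if name not in STAGES:
        raise ValueError(f"unknown stage {name!r}")
    os.makedirs(out_dir, exist_ok=True)
    return STAGES[name](manifest, out_dir)
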