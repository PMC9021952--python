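"""Deterministic synthetic-data generators.

Everything the pipeline consumes — nested toy geographies
(blocks → tracts → counties → state), park/hospital point layers, a
connected road grid, spatially autocorrelated attribute fields, and
log-normal income samples — can be generated here from a seed, so the full
stack is exercisable without any external download. The geographies are
square grids rather than census shapes; attribute fields use a
simultaneous-autoregressive (SAR) scheme so their spatial structure is
known in closed form.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry import LineString, Point, box

from .context import AdjacencyMap, RoadNetwork
from .geojson import Feature, FeatureLayer
from .lattice import Extent
from .spatial_stats import SpatialWeights

__all__ = [
    "ToyGeography",
    "make_grid_geography",
    "make_feature_layers",
    "make_autocorrelated_field",
    "plant_cluster",
    "compute_gini",
]


@dataclass
class ToyGeography:
    """Nested square-grid geography with hierarchical codes.

    Codes nest by prefix: state ``S``, county ``S-C<r>_<c>``, tract
    ``<county>-T<r>``, block ``<tract>-B<c>``.
    """

    extent: Extent
    blocks: FeatureLayer
    tracts: FeatureLayer
    counties: FeatureLayer
    state: FeatureLayer
    cell_m: float

    def layer(self, level: str) -> FeatureLayer:
        return {
            "block": self.blocks,
            "tract": self.tracts,
            "county": self.counties,
            "state": self.state,
        }[level]


def make_grid_geography(
    n_rows: int, n_cols: int, cell_km: float = 1.0, blocks_per_county: int = 1
) -> ToyGeography:
    """Square-grid geography of ``n_rows × n_cols`` block cells.

    ``blocks_per_county`` must be a perfect square s²; counties tile s×s
    blocks (grid dimensions must divide evenly), tracts are the s-block
    rows within each county. County areas are blocks_per_county × cell
    area by construction.
    """
    if n_rows <= 0 or n_cols <= 0 or cell_km <= 0:
        raise ValueError("dimensions must be positive")
    s = int(round(blocks_per_county**0.5))
    if s * s != blocks_per_county:
        raise ValueError("blocks_per_county must be a perfect square")
    if n_rows % s or n_cols % s:
        raise ValueError("grid dimensions must be divisible by sqrt(blocks_per_county)")
    cell = cell_km * 1000.0
    extent = Extent(0.0, 0.0, n_cols * cell, n_rows * cell)

    blocks, tracts, counties = [], [], []
    for cr in range(n_rows // s):
        for cc in range(n_cols // s):
            county_code = f"S-C{cr}_{cc}"
            counties.append(
                Feature(
                    box(cc * s * cell, cr * s * cell, (cc + 1) * s * cell,
                        (cr + 1) * s * cell),
                    {"code": county_code},
                )
            )
            for tr in range(s):
                tract_code = f"{county_code}-T{tr}"
                row = cr * s + tr
                tracts.append(
                    Feature(
                        box(cc * s * cell, row * cell, (cc + 1) * s * cell,
                            (row + 1) * cell),
                        {"code": tract_code},
                    )
                )
                for bc in range(s):
                    col = cc * s + bc
                    blocks.append(
                        Feature(
                            box(col * cell, row * cell, (col + 1) * cell,
                                (row + 1) * cell),
                            {"code": f"{tract_code}-B{bc}"},
                        )
                    )
    state = FeatureLayer([Feature(extent.as_polygon(), {"code": "S"})])
    return ToyGeography(
        extent, FeatureLayer(blocks), FeatureLayer(tracts),
        FeatureLayer(counties), state, cell,
    )


def make_feature_layers(
    geo: ToyGeography,
    seed: int,
    n_parks: int = 12,
    n_hospitals: int = 4,
    road_speed_kmh: float = 60.0,
) -> tuple[FeatureLayer, FeatureLayer, RoadNetwork]:
    """Random park/hospital points and a connected road grid skeleton.

    Roads run along every county boundary line (a lattice skeleton), so the
    network is connected by construction; all edges carry one speed.
    """
    rng = np.random.default_rng(seed)
    ext = geo.extent

    def random_points(n: int, kind: str) -> FeatureLayer:
        xs = rng.uniform(ext.min_x, ext.max_x, n)
        ys = rng.uniform(ext.min_y, ext.max_y, n)
        return FeatureLayer(
            Feature(Point(x, y), {"kind": kind, "id": i})
            for i, (x, y) in enumerate(zip(xs, ys))
        )

    parks = random_points(n_parks, "park")
    hospitals = random_points(n_hospitals, "hospital")

    # grid skeleton along county lines
    county_cell = None
    for f in geo.counties:
        minx, miny, maxx, maxy = f.geometry.bounds
        county_cell = maxx - minx
        break
    step = county_cell or geo.cell_m
    xs = np.arange(ext.min_x, ext.max_x + step / 2, step)
    ys = np.arange(ext.min_y, ext.max_y + step / 2, step)
    node_id = {}
    rows = []
    for i, y in enumerate(ys):
        for j, x in enumerate(xs):
            node_id[(i, j)] = len(rows)
            rows.append((len(rows), float(x), float(y)))
    nodes = pd.DataFrame(rows, columns=["node_id", "x", "y"])
    erows = []
    for i in range(len(ys)):
        for j in range(len(xs)):
            if j + 1 < len(xs):
                erows.append((node_id[(i, j)], node_id[(i, j + 1)],
                              float(xs[j + 1] - xs[j]), road_speed_kmh))
            if i + 1 < len(ys):
                erows.append((node_id[(i, j)], node_id[(i + 1, j)],
                              float(ys[i + 1] - ys[i]), road_speed_kmh))
    edges = pd.DataFrame(erows, columns=["u", "v", "length_m", "speed_kmh"])
    return parks, hospitals, RoadNetwork(nodes, edges)


def roads_as_layer(network: RoadNetwork) -> FeatureLayer:
    """Road edges as a LineString layer (for density tallies and export)."""
    xy = network.nodes.set_index("node_id")[["x", "y"]]
    feats = []
    for r in network.edges.itertuples(index=False):
        a = xy.loc[int(r.u)]
        b = xy.loc[int(r.v)]
        feats.append(
            Feature(
                LineString([(a.x, a.y), (b.x, b.y)]),
                {"length_m": float(r.length_m), "speed_kmh": float(r.speed_kmh)},
            )
        )
    return FeatureLayer(feats)


def make_autocorrelated_field(
    adjacency: AdjacencyMap | SpatialWeights, rho: float, seed: int
) -> pd.Series:
    """Simultaneous-autoregressive draw x = (I − ρW)⁻¹ ε, ε ~ N(0, 1).

    W is the row-standardised contiguity matrix, so any |ρ| < 1 is inside
    the stationary region; ρ = 0 gives i.i.d. standard normals.
    """
    if not abs(rho) < 1:
        raise ValueError("rho must satisfy |rho| < 1 (spectral radius bound)")
    if isinstance(adjacency, AdjacencyMap):
        from .spatial_stats import build_weights

        w = build_weights(adjacency, standardize="row")
    else:
        w = adjacency
    rng = np.random.default_rng(seed)
    eps = rng.standard_normal(w.n)
    if rho == 0.0:
        x = eps
    else:
        m = np.eye(w.n) - rho * w.dense()
        x = np.linalg.solve(m, eps)
    return pd.Series(x, index=pd.Index(w.ids, name="code"))


def plant_cluster(values: pd.Series, units: list[str], delta: float) -> pd.Series:
    """Shift the given units' values by delta; leave everything else alone."""
    missing = [u for u in units if u not in values.index]
    if missing:
        raise KeyError(f"unknown units: {missing[:5]}")
    out = values.copy()
    out.loc[units] = out.loc[units] + delta
    return out


def compute_gini(incomes) -> float:
    """Gini coefficient via the mean absolute difference:
    G = Σ_i Σ_j |x_i − x_j| / (2 n² x̄). Scale-invariant, in [0, 1)."""
    x = np.asarray(incomes, dtype=float)
    if x.size == 0 or (x < 0).any():
        raise ValueError("incomes must be non-negative and non-empty")
    mean = x.mean()
    if mean <= 0:
        raise ValueError("mean income must be positive")
    # O(n log n) form: G = (2 Σ i·x_(i) / (n Σ x)) − (n+1)/n
    xs = np.sort(x)
    n = x.size
    i = np.arange(1, n + 1)
    return float(2.0 * (i * xs).sum() / (n * xs.sum()) - (n + 1.0) / n)


def lognormal_incomes(n: int, seed: int, mu: float = 10.5, sigma: float = 0.7):
    """Synthetic household incomes, log-normal (heavier right tail, like
    real income distributions)."""
    rng = np.random.default_rng(seed)
    return rng.lognormal(mean=mu, sigma=sigma, size=n)
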