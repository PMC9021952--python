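import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from hextable import (
    AdjacencyMap,
    AttributeMetadata,
    BigTable,
    Extent,
    LatticeSpec,
    PointTable,
    SourceRecord,
    generate_hex_lattice,
    proximal_polygons,
)


def grid_adjacency(n_rows: int, n_cols: int, queen: bool = False) -> AdjacencyMap:
    """Independent rook/queen adjacency for a regular grid of unit codes
    ``r{i}c{j}``, built by index arithmetic (no geometry involved)."""
    steps = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    if queen:
        steps += [(-1, -1), (-1, 1), (1, -1), (1, 1)]
    first = {}
    for i in range(n_rows):
        for j in range(n_cols):
            nb = set()
            for di, dj in steps:
                if 0 <= i + di < n_rows and 0 <= j + dj < n_cols:
                    nb.add(f"r{i + di}c{j + dj}")
            first[f"r{i}c{j}"] = nb
    second = {}
    for c, nbrs in first.items():
        s = set()
        for n in nbrs:
            s |= first[n]
        second[c] = s - nbrs - {c}
    return AdjacencyMap(first, second)


def path_adjacency(n: int) -> AdjacencyMap:
    """Adjacency of a simple path u0–u1–…–u(n−1)."""
    first = {
        f"u{i}": {f"u{j}" for j in (i - 1, i + 1) if 0 <= j < n} for i in range(n)
    }
    second = {}
    for c, nbrs in first.items():
        s = set()
        for m in nbrs:
            s |= first[m]
        second[c] = s - nbrs - {c}
    return AdjacencyMap(first, second)


def point_table(xy, extent: Extent) -> PointTable:
    xy = np.asarray(xy, dtype=float)
    df = pd.DataFrame(
        {
            "point_id": np.arange(len(xy)),
            "x": xy[:, 0],
            "y": xy[:, 1],
            "origin_flag": "lattice",
            "proximal_area_m2": np.nan,
        }
    )
    return PointTable(df, extent)


@pytest.fixture
def small_bigtable():
    """9 points on a 3×3 grid over a 3 km square with one registered source
    and a county-level geography of 3 vertical strips A/B/C."""
    extent = Extent(0, 0, 3000, 3000)
    xy = [(500 + 1000 * j, 500 + 1000 * i) for i in range(3) for j in range(3)]
    pt = point_table(xy, extent)
    pt = proximal_polygons(pt)
    codes = []
    for x in pt.df["x"]:
        codes.append("A" if x < 1000 else ("B" if x < 2000 else "C"))
    pt.df["geo_county"] = codes
    bt = BigTable(pt)
    bt.register_source(SourceRecord("src1", name="toy source", url="file://toy"))
    return bt


def register_numeric(bt: BigTable, attr_id: str, values, kind="other", **kw):
    bt.register_attribute(
        AttributeMetadata(attr_id=attr_id, source_id="src1", kind=kind, **kw)
    )
    bt.data[attr_id] = np.asarray(values, dtype=object)
    return attr_id
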