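"""The query engine: text predicates over big-table columns, boolean
combinations, and contextual neighbour extraction."""

import numpy as np

from hextable import (
    AttributeMetadata, BigTable, SourceRecord, adjacency_orders,
    assign_geography, evaluate, generate_hex_lattice, make_grid_geography,
    parse_query, query_contextual, serialize,
)
from hextable.lattice import LatticeSpec

geo = make_grid_geography(6, 6, cell_km=1.0, blocks_per_county=4)
pt = generate_hex_lattice(geo.extent, LatticeSpec(spacing_m=400))
pt = assign_geography(pt, geo.counties, "county")

bt = BigTable(pt)
bt.register_source(SourceRecord("ctx", name="derived context"))
rng = np.random.default_rng(0)
for name, kind in [("dist_park", "distance_m"), ("road_density", "density"),
                   ("tt_hospital", "time_min")]:
    bt.register_attribute(AttributeMetadata(
        attr_id=name, source_id="ctx", iso_category="location", kind=kind))
bt.data["dist_park"] = rng.uniform(0, 1200, len(pt))
bt.data["road_density"] = rng.uniform(0, 3000, len(pt))
bt.data["tt_hospital"] = rng.uniform(0, 40, len(pt))

# a proximity + density + travel-time query, parsed from text
expr = parse_query(
    "dist_park > 400 AND road_density > 1500 AND tt_hospital <= 15"
)
sel = evaluate(bt, expr)
print(f"{serialize(expr)}\n  -> {len(sel)} of {len(pt)} points selected")

# simple-geography query on a key column, combined with NOT
sel2 = evaluate(bt, parse_query("county = 'S-C0_0' AND NOT tt_hospital > 15"))
print(f"county S-C0_0 within 15 min of a hospital: {len(sel2)} points")

# contextual query: summarize an attribute over the counties surrounding a
# seed cluster (first-order ring, seeds excluded)
adj = adjacency_orders(geo.counties)
table, report = query_contextual(
    bt, "county", adj, ["S-C1_1", "S-C1_2"], order="1",
    attr_ids=["dist_park", "tt_hospital"],
)
print(f"ring around 2-county cluster: {len(table)} neighbouring counties")
print(table.round(1).to_string())
# Each row is a surrounding county's mean value — the "what is around these
# places" question answered from precomputed columns.
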