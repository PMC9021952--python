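"""Context measures: distance to features, gridded density, adjacency
orders, network travel time, and aggregation to geographies."""

import numpy as np

from hextable import (
    Extent, LatticeSpec, adjacency_orders, aggregate_by_geography,
    density_grid, distance_to_nearest, generate_hex_lattice,
    make_feature_layers, make_grid_geography, travel_time,
)
from hextable.fixtures import roads_as_layer

# toy geography: 6×6 km state, 3×3 counties of 2×2 blocks
geo = make_grid_geography(6, 6, cell_km=1.0, blocks_per_county=4)
parks, hospitals, roads = make_feature_layers(geo, seed=42, n_parks=8,
                                              n_hospitals=3)
pt = generate_hex_lattice(geo.extent, LatticeSpec(spacing_m=500))

# proximity: straight-line meters to the nearest park
d_park = distance_to_nearest(pt, parks)
print(f"distance to nearest park: median {np.median(d_park):.0f} m, "
      f"max {d_park.max():.0f} m")

# density: road length per km² on a 1-km artificial grid
grid = density_grid(roads_as_layer(roads), geo.extent, 1000.0, "line_length")
print(f"road density grid: mean {grid.values.mean():.0f} m/km², "
      f"total length {grid.total():.0f} m")

# adjacency context: first and second-order county neighbours
adj = adjacency_orders(geo.counties)
c = "S-C1_1"  # the center county
print(f"{c}: {len(adj.first_order[c])} first-order, "
      f"{len(adj.second_order[c])} second-order neighbours")

# accessibility: minutes to the nearest hospital over the road network
tt = travel_time(pt, roads, hospitals, fallback_speed_kmh=40.0)
print(f"travel time to hospital: median {np.median(tt):.1f} min, "
      f"within 15 min: {(tt <= 15).mean():.0%} of points")

# geographic summary: mean distance-to-park per county
from hextable import assign_geography
pt = assign_geography(pt, geo.counties, "county")
summary = aggregate_by_geography(pt, d_park, level="county", stat="mean")
print("mean distance to park by county (m):")
print(summary.round(0).to_string())
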