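"""Context measures: distance, gridded density, adjacency orders, network
travel time, geographic aggregation."""

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import LineString, Point, box

from hextable import (
    Extent,
    Feature,
    FeatureLayer,
    RoadNetwork,
    adjacency_orders,
    aggregate_by_geography,
    density_grid,
    distance_to_nearest,
    travel_time,
)
from hextable.context import EmptyLayerError, attach_grid_values

from conftest import point_table


def pts_layer(coords, **props):
    return FeatureLayer(Feature(Point(x, y), dict(props)) for x, y in coords)


class TestDistance:
    def test_coincident_is_zero_and_345_triangle(self):
        pt = point_table([(0, 0), (3, 4)], Extent(-1, -1, 20, 20))
        feats = pts_layer([(3, 4), (10, 0)])
        d = distance_to_nearest(pt, feats)
        assert d[1] == 0.0
        assert d[0] == pytest.approx(5.0)  # min(5, 10)

    def test_empty_layer_errors(self):
        pt = point_table([(0, 0)], Extent(-1, -1, 1, 1))
        with pytest.raises(EmptyLayerError):
            distance_to_nearest(pt, FeatureLayer([]))

    def test_matches_exhaustive_min_over_pairs(self):
        rng = np.random.default_rng(3)
        xy = rng.uniform(0, 1000, (100, 2))
        fxy = rng.uniform(0, 1000, (20, 2))
        pt = point_table(xy, Extent(0, 0, 1000, 1000))
        d = distance_to_nearest(pt, pts_layer(fxy))
        brute = np.sqrt(
            ((xy[:, None, :] - fxy[None, :, :]) ** 2).sum(axis=2)
        ).min(axis=1)
        assert np.allclose(d, brute)


class TestDensityGrid:
    def test_single_point_in_unit_km_cell(self):
        ext = Extent(0, 0, 1000, 1000)
        g = density_grid(pts_layer([(500, 500)]), ext, 1000.0, "point_count")
        assert g.values.shape == (1, 1)
        assert g.values[0, 0] == pytest.approx(1.0)  # 1 per km²

    def test_line_split_across_two_cells(self):
        ext = Extent(0, 0, 2000, 1000)
        line = FeatureLayer([Feature(LineString([(0, 500), (2000, 500)]), {})])
        g = density_grid(line, ext, 1000.0, "line_length")
        assert np.allclose(g.values, [[1000.0, 1000.0]])  # m per km²

    def test_empty_cells_zero_and_conservation(self):
        rng = np.random.default_rng(7)
        ext = Extent(0, 0, 5000, 5000)
        coords = rng.uniform(0, 5000, (40, 2))
        g = density_grid(pts_layer(coords), ext, 1000.0, "point_count")
        assert g.total() == pytest.approx(40, rel=1e-6)
        assert (g.values >= 0).all() and (g.values == 0).any()

    def test_line_length_conservation(self):
        ext = Extent(0, 0, 3000, 3000)
        rng = np.random.default_rng(1)
        feats = []
        total = 0.0
        for _ in range(10):
            a = rng.uniform(0, 3000, 2)
            b = rng.uniform(0, 3000, 2)
            feats.append(Feature(LineString([a, b]), {}))
            total += float(np.hypot(*(b - a)))
        g = density_grid(FeatureLayer(feats), ext, 500.0, "line_length")
        assert g.total() == pytest.approx(total, rel=1e-6)

    def test_per_point_attribution(self):
        ext = Extent(0, 0, 2000, 1000)
        g = density_grid(pts_layer([(100, 100)]), ext, 1000.0, "point_count")
        pt = point_table([(500, 500), (1500, 500)], ext)
        vals = attach_grid_values(pt, g)
        assert vals[0] == pytest.approx(1.0) and vals[1] == 0.0


def square_grid_layer(n, cell=10.0):
    feats = []
    for i in range(n):
        for j in range(n):
            feats.append(
                Feature(box(j * cell, i * cell, (j + 1) * cell, (i + 1) * cell),
                        {"code": f"r{i}c{j}"})
            )
    return FeatureLayer(feats)


class TestAdjacency:
    def test_3x3_center_queen(self):
        amap = adjacency_orders(square_grid_layer(3), "queen")
        assert amap.first_order["r1c1"] == {
            "r0c0", "r0c1", "r0c2", "r1c0", "r1c2", "r2c0", "r2c1", "r2c2"
        }
        assert amap.second_order["r1c1"] == set()

    def test_3x3_corner_queen(self):
        amap = adjacency_orders(square_grid_layer(3), "queen")
        assert amap.first_order["r0c0"] == {"r0c1", "r1c0", "r1c1"}
        assert amap.second_order["r0c0"] == {
            "r0c2", "r1c2", "r2c0", "r2c1", "r2c2"
        }

    def test_rook_excludes_corner_touch(self):
        amap = adjacency_orders(square_grid_layer(3), "rook")
        assert amap.first_order["r1c1"] == {"r0c1", "r1c0", "r1c2", "r2c1"}
        assert "r0c0" not in amap.first_order["r1c1"]

    def test_single_polygon(self):
        layer = FeatureLayer([Feature(box(0, 0, 1, 1), {"code": "only"})])
        amap = adjacency_orders(layer)
        assert amap.first_order["only"] == set()
        assert amap.second_order["only"] == set()

    @pytest.mark.parametrize("n", [4, 7])
    def test_matches_index_arithmetic_enumeration(self, n):
        from conftest import grid_adjacency

        got = adjacency_orders(square_grid_layer(n), "queen")
        expect = grid_adjacency(n, n, queen=True)
        assert got.first_order == expect.first_order
        assert got.second_order == expect.second_order

    def test_symmetry_and_disjointness_invariants(self):
        amap = adjacency_orders(square_grid_layer(6), "queen")
        amap.validate()  # raises on violation


def simple_network():
    nodes = pd.DataFrame(
        {"node_id": [0, 1], "x": [0.0, 1000.0], "y": [0.0, 0.0]}
    )
    edges = pd.DataFrame(
        {"u": [0], "v": [1], "length_m": [1000.0], "speed_kmh": [60.0]}
    )
    return RoadNetwork(nodes, edges)


class TestTravelTime:
    def test_single_edge_one_minute(self):
        net = simple_network()
        pt = point_table([(0, 0)], Extent(-10, -10, 2000, 10))
        fac = pts_layer([(1000, 0)])
        t = travel_time(pt, net, fac)
        assert t[0] == pytest.approx(1.0)  # 1 km at 60 km/h

    def test_facility_at_snap_node_is_zero(self):
        net = simple_network()
        pt = point_table([(0, 0)], Extent(-10, -10, 2000, 10))
        t = travel_time(pt, net, pts_layer([(0, 0)]))
        assert t[0] == pytest.approx(0.0)

    def test_no_network_straight_line_fallback(self):
        pt = point_table([(0, 0)], Extent(-10, -10, 2000, 2000))
        t = travel_time(pt, None, pts_layer([(1000, 0)]), fallback_speed_kmh=60.0)
        assert t[0] == pytest.approx(1.0)

    def test_no_facilities_errors(self):
        pt = point_table([(0, 0)], Extent(-1, -1, 1, 1))
        with pytest.raises(EmptyLayerError):
            travel_time(pt, None, FeatureLayer([]))

    def test_matches_exhaustive_path_enumeration(self):
        import itertools
        import networkx as nx

        rng = np.random.default_rng(9)
        # 6-node network: 5-cycle + spur, random speeds
        coords = [(0, 0), (1000, 0), (2000, 500), (1000, 1500), (0, 1000), (3000, 500)]
        pairs = [(0, 1), (1, 2), (2, 3), (3, 4), (4, 0), (2, 5)]
        nodes = pd.DataFrame(
            [(i, *c) for i, c in enumerate(coords)], columns=["node_id", "x", "y"]
        )
        edges = pd.DataFrame(
            [
                (u, v, float(np.hypot(coords[u][0] - coords[v][0],
                                      coords[u][1] - coords[v][1])),
                 float(rng.uniform(30, 90)))
                for u, v in pairs
            ],
            columns=["u", "v", "length_m", "speed_kmh"],
        )
        net = RoadNetwork(nodes, edges)
        fac = pts_layer([coords[5]])
        pt = point_table([coords[0]], Extent(-100, -100, 4000, 2000))
        got = travel_time(pt, net, fac)[0]
        g = net.graph()
        best = min(
            sum(g[a][b]["minutes"] for a, b in zip(p[:-1], p[1:]))
            for p in nx.all_simple_paths(g, 0, 5)
        )
        assert got == pytest.approx(best)

    def test_lower_bound_euclidean_over_max_speed(self):
        rng = np.random.default_rng(21)
        net = simple_network()
        xy = rng.uniform(-10, 2000, (50, 2))
        pt = point_table(xy, Extent(-10, -10, 2100, 2100))
        fac_xy = [(1000.0, 0.0)]
        t = travel_time(pt, net, pts_layer(fac_xy), fallback_speed_kmh=50.0)
        vmax = max(net.max_speed_kmh, 50.0)
        euclid = np.hypot(xy[:, 0] - 1000.0, xy[:, 1])
        bound = euclid / 1000.0 / vmax * 60.0
        assert (t >= bound - 1e-9).all()


class TestAggregation:
    def test_constant_attribute_mean(self, small_bigtable):
        pt = small_bigtable.points
        vals = np.full(len(pt), 3.25)
        out = aggregate_by_geography(pt, vals, level="county", stat="mean")
        assert np.allclose(out.to_numpy(), 3.25)

    def test_hand_computed_stats(self):
        pt = point_table([(1, 1), (2, 1), (3, 1)], Extent(0, 0, 10, 10))
        pt.df["geo_u"] = "one"
        vals = [2, 4, 9]
        expect = {"mean": 5.0, "sum": 15.0, "min": 2.0, "max": 9.0, "count": 3.0}
        for stat, e in expect.items():
            out = aggregate_by_geography(pt, vals, level="u", stat=stat)
            assert out["one"] == pytest.approx(e)

    def test_empty_unit_is_null(self):
        layer = FeatureLayer(
            [Feature(box(0, 0, 1, 1), {"code": "a"}),
             Feature(box(5, 5, 6, 6), {"code": "b"})]
        )
        pt = point_table([(0.5, 0.5)], Extent(0, 0, 10, 10))
        out = aggregate_by_geography(pt, [1.0], layer=layer, stat="mean")
        assert out["a"] == 1.0 and np.isnan(out["b"])

    def test_unknown_stat(self, small_bigtable):
        with pytest.raises(ValueError):
            aggregate_by_geography(
                small_bigtable.points, np.zeros(9), level="county", stat="median"
            )

    def test_linear_field_mean_equals_centroid_value(self):
        """Unweighted mean of ax+by over a symmetric point set equals the
        field at the point-centroid."""
        xy = [(x, y) for x in (10, 20, 30) for y in (5, 15, 25)]
        pt = point_table(xy, Extent(0, 0, 100, 100))
        pt.df["geo_u"] = "u"
        a, b = 2.0, -3.0
        vals = [a * x + b * y for x, y in xy]
        out = aggregate_by_geography(pt, vals, level="u", stat="mean")
        cx = np.mean([p[0] for p in xy])
        cy = np.mean([p[1] for p in xy])
        assert out["u"] == pytest.approx(a * cx + b * cy, abs=1e-6)
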