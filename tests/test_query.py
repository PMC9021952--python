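"""Query engine: predicate evaluation vs brute-force scans, null
semantics, boolean algebra, parsing round trips, contextual queries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from hextable import (
    AttributeMetadata,
    BigTable,
    Predicate,
    evaluate,
    parse_query,
    query_contextual,
    serialize,
)
from hextable.bigtable import CatalogError
from hextable.query import And, Not, Or, QuerySyntaxError, TrueExpr

from conftest import grid_adjacency, register_numeric


class TestEvaluate:
    def test_empty_expression_selects_all(self, small_bigtable):
        sel = evaluate(small_bigtable, TrueExpr())
        assert sel.point_ids.tolist() == list(range(9))

    def test_contradiction_is_empty(self, small_bigtable):
        bt = small_bigtable
        register_numeric(bt, "a", range(9))
        p = Predicate("a", ">", 4)
        sel = evaluate(bt, And((p, Not(p))))
        assert len(sel) == 0

    def test_null_never_satisfies_any_comparator(self, small_bigtable):
        bt = small_bigtable
        register_numeric(bt, "a", [1, None, 3, None, 5, None, 7, None, 9])
        for comp, val in [("<", 100), (">", -100), ("=", 1), ("!=", 1), ("<=", 9)]:
            sel = evaluate(bt, Predicate("a", comp, val))
            assert not {1, 3, 5, 7}.intersection(sel.point_ids)

    def test_explicit_null_test_via_in(self, small_bigtable):
        bt = small_bigtable
        register_numeric(bt, "a", [1, None, 3, None, 5, None, 7, None, 9])
        sel = evaluate(bt, Predicate("a", "in", (None,)))
        assert sel.point_ids.tolist() == [1, 3, 5, 7]

    def test_geography_key_pseudo_column(self, small_bigtable):
        sel = evaluate(small_bigtable, Predicate("county", "=", "B"))
        keys = small_bigtable.points.geography_keys("county")
        assert sel.point_ids.tolist() == [
            int(i) for i, k in zip(small_bigtable.points.point_ids, keys) if k == "B"
        ]

    def test_unknown_attribute_and_bad_comparator(self, small_bigtable):
        bt = small_bigtable
        with pytest.raises(CatalogError):
            evaluate(bt, Predicate("ghost", "=", 1))
        bt.register_attribute(
            AttributeMetadata(attr_id="cat", source_id="src1",
                              iso_category="society", kind="categorical")
        )
        bt.data["cat"] = np.array(["x"] * 9, dtype=object)
        with pytest.raises(CatalogError):
            evaluate(bt, Predicate("cat", ">", 1))

    def test_three_conjunct_matches_full_scan(self, small_bigtable):
        """Complex-variable style query: three numeric thresholds ANDed."""
        rng = np.random.default_rng(0)
        bt = small_bigtable
        a = rng.uniform(0, 100, 9)
        b = rng.uniform(0, 50, 9)
        c = rng.uniform(0, 10, 9)
        register_numeric(bt, "pct_a", a)
        register_numeric(bt, "pct_b", b)
        register_numeric(bt, "pct_c", c)
        expr = And((Predicate("pct_a", ">", 30), Predicate("pct_b", ">", 15),
                    Predicate("pct_c", ">", 5)))
        sel = evaluate(bt, expr)
        expect = [i for i in range(9) if a[i] > 30 and b[i] > 15 and c[i] > 5]
        assert sel.point_ids.tolist() == expect

    def test_de_morgan_equivalence(self, small_bigtable):
        bt = small_bigtable
        rng = np.random.default_rng(4)
        register_numeric(bt, "u", rng.uniform(0, 1, 9))
        register_numeric(bt, "v", rng.uniform(0, 1, 9))
        a = Predicate("u", ">", 0.5)
        b = Predicate("v", "<=", 0.3)
        lhs = evaluate(bt, Not(And((a, b)))).point_ids
        rhs = evaluate(bt, Or((Not(a), Not(b)))).point_ids
        assert lhs.tolist() == rhs.tolist()

    def test_threshold_monotonicity(self, small_bigtable):
        bt = small_bigtable
        register_numeric(bt, "m", np.linspace(0, 1, 9))
        prev = None
        for thr in [0.1, 0.3, 0.5, 0.7, 0.9]:
            cur = set(evaluate(bt, Predicate("m", ">=", thr)).point_ids)
            if prev is not None:
                assert cur <= prev
            prev = cur


def random_bigtable(n_points=10_000, n_attrs=20, seed=0):
    import pandas as pd

    from hextable import Extent, SourceRecord
    from conftest import point_table

    rng = np.random.default_rng(seed)
    xy = rng.uniform(0, 10000, (n_points, 2))
    pt = point_table(xy, Extent(0, 0, 10000, 10000))
    pt.df["proximal_area_m2"] = 1.0
    bt = BigTable(pt)
    bt.register_source(SourceRecord("src1", name="random fixture"))
    cols = {}
    for k in range(n_attrs):
        vals = rng.uniform(0, 100, n_points)
        vals[rng.random(n_points) < 0.05] = np.nan  # planted nulls
        name = f"v{k:02d}"
        bt.register_attribute(
            AttributeMetadata(attr_id=name, source_id="src1",
                              iso_category="society", kind="rate")
        )
        bt.data[name] = vals
        cols[name] = vals
    return bt, cols


def random_expr(rng, attrs, depth=0):
    if depth >= 4 or rng.random() < 0.4:
        a = attrs[rng.integers(len(attrs))]
        comp = ["<", "<=", ">", ">=", "=", "!="][rng.integers(6)]
        return Predicate(a, comp, float(np.round(rng.uniform(0, 100), 2)))
    r = rng.random()
    if r < 0.4:
        return And(tuple(random_expr(rng, attrs, depth + 1)
                         for _ in range(rng.integers(2, 4))))
    if r < 0.8:
        return Or(tuple(random_expr(rng, attrs, depth + 1)
                        for _ in range(rng.integers(2, 4))))
    return Not(random_expr(rng, attrs, depth + 1))


def brute_mask(expr, cols, n):
    if isinstance(expr, TrueExpr):
        return np.ones(n, dtype=bool)
    if isinstance(expr, Predicate):
        x = cols[expr.attr_id]
        v = expr.value
        with np.errstate(invalid="ignore"):
            m = {
                "<": x < v, "<=": x <= v, ">": x > v, ">=": x >= v,
                "=": x == v, "!=": x != v,
            }[expr.comparator]
        return np.where(np.isnan(x), False, m)
    if isinstance(expr, And):
        out = np.ones(n, dtype=bool)
        for p in expr.parts:
            out &= brute_mask(p, cols, n)
        return out
    if isinstance(expr, Or):
        out = np.zeros(n, dtype=bool)
        for p in expr.parts:
            out |= brute_mask(p, cols, n)
        return out
    return ~brute_mask(expr.part, cols, n)


class TestOracleEquivalence:
    def test_random_expressions_match_brute_force(self):
        bt, cols = random_bigtable(n_points=2000, seed=1)
        rng = np.random.default_rng(2)
        attrs = sorted(cols)
        n = len(bt.points)
        for _ in range(50):
            expr = random_expr(rng, attrs)
            got = evaluate(bt, expr).point_ids
            expect = np.where(brute_mask(expr, cols, n))[0]
            assert np.array_equal(got, expect), serialize(expr)


class TestParser:
    def test_two_conjunct_tree(self):
        expr = parse_query("a > 1 AND b <= 2")
        assert isinstance(expr, And) and len(expr.parts) == 2
        assert expr.parts[0] == Predicate("a", ">", 1)
        assert expr.parts[1] == Predicate("b", "<=", 2)

    def test_unbalanced_parenthesis(self):
        with pytest.raises(QuerySyntaxError):
            parse_query("(a > 1 AND b <= 2")

    def test_in_set_and_null(self):
        expr = parse_query("county in ['A', 'B', null]")
        assert expr == Predicate("county", "in", ("A", "B", None))

    def test_precedence_or_over_and(self):
        expr = parse_query("a = 1 OR b = 2 AND c = 3")
        assert isinstance(expr, Or)
        assert isinstance(expr.parts[1], And)

    @given(st.integers(0, 10**6))
    @settings(max_examples=60, deadline=None)
    def test_parse_serialize_fixpoint(self, seed):
        rng = np.random.default_rng(seed)
        attrs = [f"v{k:02d}" for k in range(5)]
        expr = random_expr(rng, attrs)
        s1 = serialize(expr)
        s2 = serialize(parse_query(s1))
        assert s1 == s2
        assert serialize(parse_query(s2)) == s2


class TestContextualQuery:
    def _bt_with_units(self, n=5):
        from hextable import Extent, SourceRecord
        from conftest import point_table

        coords, codes = [], []
        for i in range(n):
            for j in range(n):
                coords.append((j * 10 + 5, i * 10 + 5))
                codes.append(f"r{i}c{j}")
        pt = point_table(coords, Extent(0, 0, 10 * n, 10 * n))
        pt.df["geo_county"] = codes
        bt = BigTable(pt)
        bt.register_source(SourceRecord("src1", name="toy"))
        register_numeric(bt, "val", np.arange(n * n, dtype=float))
        return bt

    def test_center_seed_order1_is_ring(self):
        bt = self._bt_with_units(3)
        adj = grid_adjacency(3, 3, queen=True)
        out, report = query_contextual(
            bt, "county", adj, ["r1c1"], order="1", attr_ids=["val"]
        )
        assert set(out.index) == {c for c in adj.first_order if c != "r1c1"}
        assert report.row_count == 8

    def test_all_seeds_empty_neighbourhood(self):
        bt = self._bt_with_units(3)
        adj = grid_adjacency(3, 3, queen=True)
        out, _ = query_contextual(
            bt, "county", adj, sorted(adj.first_order), order="1+2",
            attr_ids=["val"],
        )
        assert len(out) == 0

    def test_cluster_of_three_seeds_matches_set_algebra(self):
        bt = self._bt_with_units(5)
        adj = grid_adjacency(5, 5, queen=True)
        seeds = ["r2c1", "r2c2", "r2c3"]
        out, _ = query_contextual(
            bt, "county", adj, seeds, order="1", attr_ids=["val"]
        )
        expect = set()
        for s in seeds:
            expect |= adj.first_order[s]
        expect -= set(seeds)
        assert set(out.index) == expect
        # values are the per-unit aggregates (one point per unit → identity)
        vals = {f"r{i}c{j}": i * 5 + j for i in range(5) for j in range(5)}
        for code in out.index:
            assert out.loc[code, "val"] == pytest.approx(vals[code])

    def test_unknown_seed_errors(self):
        bt = self._bt_with_units(3)
        adj = grid_adjacency(3, 3, queen=True)
        with pytest.raises(KeyError):
            query_contextual(bt, "county", adj, ["nope"], attr_ids=["val"])
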