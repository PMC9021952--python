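"""Query engine over big-table columns.

Because context measures (distance, density, travel time, adjacency) are
precomputed into columns, all query families — simple geography, simple
variable, complex boolean combinations, density, proximity, and
travel-time thresholds — reduce to column predicates evaluated against the
flat table. Null values never satisfy a predicate; an explicit null test
is available via the ``in`` comparator with ``null`` in its value set.

A small text grammar is provided::

    expr   := term ( OR term )*
    term   := factor ( AND factor )*
    factor := NOT factor | '(' expr ')' | pred
    pred   := attr op value | attr 'in' '[' value (',' value)* ']'
    op     := = | != | < | <= | > | >=
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
import pandas as pd

from .bigtable import BigTable, CatalogError, ExtractReport
from .context import AdjacencyMap, aggregate_by_geography

__all__ = [
    "Predicate",
    "And",
    "Or",
    "Not",
    "TrueExpr",
    "QueryExpr",
    "Selection",
    "evaluate",
    "parse_query",
    "serialize",
    "query_contextual",
    "QuerySyntaxError",
]

_COMPARATORS = {"=", "!=", "<", "<=", ">", ">=", "in"}
_ORDERED = {"<", "<=", ">", ">="}
_NUMERIC_KINDS = {"count", "density", "rate", "distance_m", "time_min", "score", "other"}


class QuerySyntaxError(ValueError):
    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


@dataclass(frozen=True)
class Predicate:
    attr_id: str
    comparator: str
    value: Any

    def __post_init__(self):
        if self.comparator not in _COMPARATORS:
            raise ValueError(f"unknown comparator {self.comparator!r}")


@dataclass(frozen=True)
class And:
    parts: tuple  # of QueryExpr


@dataclass(frozen=True)
class Or:
    parts: tuple


@dataclass(frozen=True)
class Not:
    part: Any


@dataclass(frozen=True)
class TrueExpr:
    """The vacuous query: selects every point."""


QueryExpr = Predicate | And | Or | Not | TrueExpr


@dataclass
class Selection:
    """Sorted point-id selection with the expression that produced it."""

    point_ids: np.ndarray
    provenance: str

    def __post_init__(self):
        self.point_ids = np.unique(np.asarray(self.point_ids, dtype=np.int64))

    def __len__(self) -> int:
        return len(self.point_ids)

    def to_csv(self, path: str) -> None:
        pd.DataFrame({"point_id": self.point_ids}).to_csv(path, index=False)


def _eval_predicate(bt: BigTable, p: Predicate) -> np.ndarray:
    meta = bt.attributes.get(p.attr_id)
    geo_col = None
    if meta is None:
        # geography-key pseudo-columns support "simple geography" queries
        if p.attr_id in bt.points.geography_levels:
            geo_col = bt.points.geography_keys(p.attr_id)
        else:
            raise CatalogError(f"unknown attribute {p.attr_id!r}")
    col = geo_col if geo_col is not None else bt.column(p.attr_id)
    if p.comparator == "in":
        values = p.value if isinstance(p.value, (list, tuple, set)) else [p.value]
        want_null = any(v is None for v in values)
        non_null = [v for v in values if v is not None]
        isnull = col.isna() | col.map(lambda v: v is None)
        mask = np.zeros(len(col), dtype=bool)
        if non_null:
            mask |= col.astype("object").isin(non_null).to_numpy() & ~isnull.to_numpy()
            # numeric coercion so 3 matches 3.0
            num = pd.to_numeric(col, errors="coerce")
            for v in non_null:
                if isinstance(v, (int, float)):
                    mask |= (num == float(v)).to_numpy()
        if want_null:
            mask |= isnull.to_numpy()
        return mask
    isnull = col.isna() | col.map(lambda v: v is None)
    if p.comparator in _ORDERED:
        if meta is not None and meta.kind == "categorical":
            raise CatalogError(
                f"ordering comparator {p.comparator!r} invalid for categorical "
                f"attribute {p.attr_id!r}"
            )
        num = pd.to_numeric(col, errors="coerce").to_numpy(dtype=float)
        v = float(p.value)
        with np.errstate(invalid="ignore"):
            mask = {
                "<": num < v,
                "<=": num <= v,
                ">": num > v,
                ">=": num >= v,
            }[p.comparator]
        return np.where(np.isnan(num), False, mask)
    # equality on mixed types: compare as numbers when both sides numeric
    if isinstance(p.value, (int, float)) and not isinstance(p.value, bool):
        num = pd.to_numeric(col, errors="coerce").to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            eq = num == float(p.value)
        eq = np.where(np.isnan(num), False, eq)
    else:
        eq = (col.astype("object").map(lambda v: str(v)) == str(p.value)).to_numpy()
        eq &= ~isnull.to_numpy()
    return eq if p.comparator == "=" else (~eq & ~isnull.to_numpy())


def _eval(bt: BigTable, expr: QueryExpr) -> np.ndarray:
    if isinstance(expr, TrueExpr):
        return np.ones(len(bt.points), dtype=bool)
    if isinstance(expr, Predicate):
        return _eval_predicate(bt, expr)
    if isinstance(expr, And):
        out = np.ones(len(bt.points), dtype=bool)
        for part in expr.parts:
            out &= _eval(bt, part)
        return out
    if isinstance(expr, Or):
        out = np.zeros(len(bt.points), dtype=bool)
        for part in expr.parts:
            out |= _eval(bt, part)
        return out
    if isinstance(expr, Not):
        return ~_eval(bt, expr.part)
    raise TypeError(f"not a query expression: {expr!r}")


def evaluate(bt: BigTable, expr: QueryExpr) -> Selection:
    """Evaluate a boolean column-predicate expression to a point selection."""
    mask = _eval(bt, expr)
    ids = bt.points.point_ids[mask]
    return Selection(ids, serialize(expr))


def serialize(expr: QueryExpr) -> str:
    if isinstance(expr, TrueExpr):
        return "TRUE"
    if isinstance(expr, Predicate):
        if expr.comparator == "in":
            vals = expr.value if isinstance(expr.value, (list, tuple)) else [expr.value]
            inner = ", ".join("null" if v is None else _fmt_value(v) for v in vals)
            return f"{expr.attr_id} in [{inner}]"
        return f"{expr.attr_id} {expr.comparator} {_fmt_value(expr.value)}"
    if isinstance(expr, And):
        return "(" + " AND ".join(serialize(p) for p in expr.parts) + ")"
    if isinstance(expr, Or):
        return "(" + " OR ".join(serialize(p) for p in expr.parts) + ")"
    if isinstance(expr, Not):
        return f"NOT {serialize(expr.part)}"
    raise TypeError(f"not a query expression: {expr!r}")


def _fmt_value(v: Any) -> str:
    if isinstance(v, str):
        return f"'{v}'"
    if isinstance(v, float) and v.is_integer():
        return str(int(v))
    return str(v)


_TOKEN_RE = re.compile(
    r"\s*(?:(?P<lpar>\()|(?P<rpar>\))|(?P<lbrack>\[)|(?P<rbrack>\])|(?P<comma>,)"
    r"|(?P<op><=|>=|!=|=|<|>)"
    r"|(?P<str>'[^']*')"
    r"|(?P<num>-?\d+(?:\.\d+)?(?:[eE][+-]?\d+)?)"
    r"|(?P<word>[A-Za-z_][A-Za-z0-9_.\-]*))"
)


def _tokenize(text: str):
    pos = 0
    tokens = []
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None or m.end() == pos:
            if text[pos:].strip() == "":
                break
            raise QuerySyntaxError(f"unexpected character {text[pos]!r}", pos)
        tokens.append((m.lastgroup, m.group().strip(), m.start()))
        pos = m.end()
    return tokens


class _Parser:
    def __init__(self, tokens, text_len: int):
        self.tokens = tokens
        self.i = 0
        self.text_len = text_len

    def peek(self):
        return self.tokens[self.i] if self.i < len(self.tokens) else None

    def next(self):
        t = self.peek()
        if t is None:
            raise QuerySyntaxError("unexpected end of input", self.text_len)
        self.i += 1
        return t

    def expect(self, kind: str):
        t = self.next()
        if t[0] != kind:
            raise QuerySyntaxError(f"expected {kind}, got {t[1]!r}", t[2])
        return t

    def parse(self) -> QueryExpr:
        if not self.tokens:
            return TrueExpr()
        expr = self.parse_or()
        t = self.peek()
        if t is not None:
            raise QuerySyntaxError(f"unexpected trailing token {t[1]!r}", t[2])
        return expr

    def parse_or(self) -> QueryExpr:
        parts = [self.parse_and()]
        while True:
            t = self.peek()
            if t and t[0] == "word" and t[1].upper() == "OR":
                self.next()
                parts.append(self.parse_and())
            else:
                break
        return parts[0] if len(parts) == 1 else Or(tuple(parts))

    def parse_and(self) -> QueryExpr:
        parts = [self.parse_factor()]
        while True:
            t = self.peek()
            if t and t[0] == "word" and t[1].upper() == "AND":
                self.next()
                parts.append(self.parse_factor())
            else:
                break
        return parts[0] if len(parts) == 1 else And(tuple(parts))

    def parse_factor(self) -> QueryExpr:
        t = self.peek()
        if t is None:
            raise QuerySyntaxError("unexpected end of input", self.text_len)
        if t[0] == "word" and t[1].upper() == "NOT":
            self.next()
            return Not(self.parse_factor())
        if t[0] == "word" and t[1].upper() == "TRUE":
            self.next()
            return TrueExpr()
        if t[0] == "lpar":
            self.next()
            inner = self.parse_or()
            tt = self.next()
            if tt[0] != "rpar":
                raise QuerySyntaxError("expected ')'", tt[2])
            return inner
        return self.parse_predicate()

    def parse_predicate(self) -> Predicate:
        t = self.expect("word")
        attr = t[1]
        op_t = self.next()
        if op_t[0] == "word" and op_t[1].lower() == "in":
            self.expect("lbrack")
            values: list[Any] = [self.parse_value(allow_null=True)]
            while True:
                tt = self.next()
                if tt[0] == "rbrack":
                    break
                if tt[0] != "comma":
                    raise QuerySyntaxError("expected ',' or ']'", tt[2])
                values.append(self.parse_value(allow_null=True))
            return Predicate(attr, "in", tuple(values))
        if op_t[0] != "op":
            raise QuerySyntaxError(f"expected comparator, got {op_t[1]!r}", op_t[2])
        value = self.parse_value()
        return Predicate(attr, op_t[1], value)

    def parse_value(self, allow_null: bool = False) -> Any:
        t = self.next()
        if t[0] == "num":
            f = float(t[1])
            return int(f) if f.is_integer() and "." not in t[1] and "e" not in t[1].lower() else f
        if t[0] == "str":
            return t[1][1:-1]
        if t[0] == "word":
            if allow_null and t[1].lower() == "null":
                return None
            return t[1]  # bare word treated as string value
        raise QuerySyntaxError(f"expected a value, got {t[1]!r}", t[2])


def parse_query(text: str) -> QueryExpr:
    """Parse the text grammar; ``parse ∘ serialize`` is a fixpoint."""
    tokens = _tokenize(text)
    return _Parser(tokens, len(text)).parse()


def query_contextual(
    bt: BigTable,
    level: str,
    adjacency: AdjacencyMap,
    seed_codes: Sequence[str],
    order: str = "1",
    attr_ids: Sequence[str] = (),
    stat: str = "mean",
) -> tuple[pd.DataFrame, ExtractReport]:
    """Aggregate attributes over the units *surrounding* seed units.

    The neighbour set is the union of the requested adjacency orders over
    all seeds, minus the seeds themselves; each attribute is summarised to
    those units with :func:`~hextable.context.aggregate_by_geography`.
    """
    known = set(adjacency.first_order)
    unknown = [s for s in seed_codes if s not in known]
    if unknown:
        raise KeyError(f"unknown seed codes: {unknown[:5]}")
    nbrs: set[str] = set()
    for s in seed_codes:
        nbrs |= adjacency.neighbors(s, order)
    nbrs -= set(seed_codes)
    out = pd.DataFrame(index=pd.Index(sorted(nbrs), name="code"))
    metas = [bt._require_attr(a) for a in attr_ids]
    for a in attr_ids:
        agg = aggregate_by_geography(
            bt.points, bt.column(a).to_numpy(), level=level, stat=stat
        )
        out[a] = agg.reindex(out.index)
    report = ExtractReport(
        selection_description=(
            f"order-{order} neighbours of {sorted(set(seed_codes))} at level {level}"
        ),
        row_count=len(out),
        attributes=metas,
        sources=[bt.sources[s] for s in sorted({m.source_id for m in metas})],
    )
    return out, report
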