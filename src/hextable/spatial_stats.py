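"""Spatial statistics: contiguity weights, global and local Moran's I with
conditional-permutation inference, and SKATER-style spatially constrained
multivariate clustering.

Global Moran's I for values x on n units with weights w is

    I = (n / S0) · Σ_ij w_ij z_i z_j / Σ_i z_i² ,   z_i = x_i − x̄,

with S0 = Σ_ij w_ij. The local decomposition is I_i = (z_i / m2)·Σ_j w_ij z_j
with m2 = Σ z² / n; under row-standardised, island-free weights the mean of
the local statistics equals the global one. Significance of each I_i is
assessed by conditional permutation: holding z_i fixed, the remaining values
are randomly reassigned to the other units, and the pseudo p-value is the
+1-corrected fraction of permuted |I_i| at least as extreme as the observed
one (two-sided). Significant units are labelled HH/LL (clusters) or HL/LH
(outliers) by the signs of z_i and its spatial lag.

SKATER regionalization prunes a minimum spanning tree of the contiguity
graph, where edge dissimilarity is squared Euclidean distance between
z-scaled attribute vectors, removing at each step the tree edge whose
removal most decreases total within-cluster sum of squared deviations.
Resulting clusters are contiguous by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .context import AdjacencyMap

logger = logging.getLogger(__name__)

__all__ = [
    "SpatialWeights",
    "LisaResult",
    "ClusterAssignment",
    "build_weights",
    "global_moran",
    "local_moran",
    "skater_cluster",
]


class DegenerateVarianceError(ValueError):
    pass


@dataclass
class SpatialWeights:
    """Neighbour structure for areal units.

    ``neighbors[i]`` holds integer positions of unit i's neighbours in
    ``ids``; ``weights[i]`` the matching weight values. Binary contiguity
    weights are symmetric; after row standardisation every non-island row
    sums to one. Units with no neighbours are islands.
    """

    ids: list[str]
    neighbors: list[np.ndarray]
    weights: list[np.ndarray]
    row_standardized: bool = False

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def islands(self) -> list[str]:
        return [self.ids[i] for i in range(self.n) if len(self.neighbors[i]) == 0]

    @property
    def s0(self) -> float:
        return float(sum(w.sum() for w in self.weights))

    def lag(self, z: np.ndarray) -> np.ndarray:
        out = np.zeros(self.n)
        for i in range(self.n):
            if len(self.neighbors[i]):
                out[i] = float(self.weights[i] @ z[self.neighbors[i]])
        return out

    def dense(self) -> np.ndarray:
        m = np.zeros((self.n, self.n))
        for i in range(self.n):
            m[i, self.neighbors[i]] = self.weights[i]
        return m

    def to_text(self) -> str:
        """Neighbour-list serialisation: one ``unit: nbr nbr …`` per line."""
        lines = []
        for i, u in enumerate(self.ids):
            nbrs = " ".join(self.ids[j] for j in self.neighbors[i])
            lines.append(f"{u}: {nbrs}".rstrip())
        return "\n".join(lines) + "\n"


def build_weights(adjacency: AdjacencyMap, standardize: str = "row") -> SpatialWeights:
    """First-order binary contiguity weights, optionally row-standardised."""
    if standardize not in ("none", "row"):
        raise ValueError(f"unknown standardization {standardize!r}")
    ids = adjacency.codes
    pos = {c: i for i, c in enumerate(ids)}
    neighbors, weights = [], []
    islands = []
    for c in ids:
        nbrs = np.array(sorted(pos[v] for v in adjacency.first_order[c]), dtype=np.int64)
        if len(nbrs) == 0:
            islands.append(c)
        w = np.ones(len(nbrs), dtype=float)
        if standardize == "row" and len(nbrs):
            w /= len(nbrs)
        neighbors.append(nbrs)
        weights.append(w)
    if islands:
        logger.warning("build_weights: %d island units: %s", len(islands), islands[:5])
    return SpatialWeights(ids, neighbors, weights, row_standardized=(standardize == "row"))


def _deviations(values, w: SpatialWeights) -> np.ndarray:
    x = np.asarray(values, dtype=float)
    if x.shape != (w.n,):
        raise ValueError(f"expected {w.n} values, got {x.shape}")
    if w.n < 3:
        raise ValueError("need at least 3 units")
    z = x - x.mean()
    if np.allclose(z, 0.0):
        raise DegenerateVarianceError("values are constant")
    return z


def global_moran(values, w: SpatialWeights) -> float:
    z = _deviations(values, w)
    num = float(z @ w.lag(z))
    return w.n / w.s0 * num / float(z @ z)


@dataclass
class LisaResult:
    """Per-unit local Moran's I with permutation inference."""

    ids: list[str]
    local_i: np.ndarray
    pseudo_p: np.ndarray
    labels: list[str]  # HH, LL, HL, LH, NS
    alpha: float
    n_perm: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"unit": self.ids, "local_i": self.local_i,
             "pseudo_p": self.pseudo_p, "label": self.labels}
        )

    def significant(self) -> np.ndarray:
        return np.array([lab != "NS" for lab in self.labels])


def _adjust_p(p: np.ndarray, method: str) -> np.ndarray:
    n = len(p)
    if method == "bonferroni":
        return np.minimum(p * n, 1.0)
    if method == "fdr_bh":
        order = np.argsort(p)
        ranked = p[order] * n / np.arange(1, n + 1)
        ranked = np.minimum.accumulate(ranked[::-1])[::-1]
        out = np.empty(n)
        out[order] = np.minimum(ranked, 1.0)
        return out
    raise ValueError(f"unknown p_adjust method {method!r}")


def local_moran(
    values,
    w: SpatialWeights,
    n_perm: int = 999,
    seed: int | None = None,
    alpha: float = 0.05,
    p_adjust: str | None = None,
) -> LisaResult:
    """Local Moran's I with conditional permutation pseudo p-values.

    For each unit the permutation distribution reassigns the other n−1
    values (without replacement) to its neighbour slots; the two-sided
    pseudo-p is ``(1 + #{|I_perm| ≥ |I_obs|}) / (1 + n_perm)``. A unit is
    labelled by the quadrant of (z_i, lag_i) when p ≤ alpha, else NS; an
    exactly-zero deviation is NS by convention. No multiple-testing
    correction is applied unless ``p_adjust`` names one ("bonferroni" or
    "fdr_bh"); labelling then uses the adjusted p-values.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be at least 99")
    z = _deviations(values, w)
    n = w.n
    m2 = float(z @ z) / n
    lag = w.lag(z)
    local_i = z / m2 * lag

    rng = np.random.default_rng(seed)
    pseudo_p = np.ones(n)
    for i in range(n):
        nbrs = w.neighbors[i]
        k = len(nbrs)
        if k == 0:
            pseudo_p[i] = 1.0
            continue
        others = np.delete(z, i)
        # k draws without replacement per permutation, vectorised
        r = rng.random((n_perm, n - 1))
        pick = np.argpartition(r, k - 1, axis=1)[:, :k]
        zperm = others[pick]
        lag_perm = zperm @ w.weights[i]
        i_perm = z[i] / m2 * lag_perm
        extreme = np.abs(i_perm) >= abs(local_i[i]) - 1e-14
        pseudo_p[i] = (1.0 + int(extreme.sum())) / (1.0 + n_perm)

    p_label = _adjust_p(pseudo_p, p_adjust) if p_adjust else pseudo_p
    labels = []
    for i in range(n):
        if p_label[i] > alpha or z[i] == 0.0 or len(w.neighbors[i]) == 0:
            labels.append("NS")
        elif z[i] > 0:
            labels.append("HH" if lag[i] > 0 else "HL")
        else:
            labels.append("LL" if lag[i] < 0 else "LH")
    return LisaResult(list(w.ids), local_i, pseudo_p, labels, alpha, n_perm)


@dataclass
class ClusterAssignment:
    """Contiguous cluster labels per unit."""

    ids: list[str]
    labels: np.ndarray  # int cluster id per unit, 0..k-1
    k: int
    within_ss: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"unit": self.ids, "cluster": self.labels})

    def members(self, c: int) -> list[str]:
        return [u for u, lab in zip(self.ids, self.labels) if lab == c]


def _component_ss(x: np.ndarray, members: np.ndarray) -> float:
    sub = x[members]
    return float(((sub - sub.mean(axis=0)) ** 2).sum())


def skater_cluster(
    ids: list[str],
    attrs: np.ndarray | pd.DataFrame,
    adjacency: AdjacencyMap,
    k: int,
) -> ClusterAssignment:
    """Spatially constrained clustering by MST pruning.

    Attributes are z-scaled per column; the contiguity graph's minimum
    spanning tree (edge weight = squared Euclidean attribute distance, ties
    broken by edge id) is cut k−1 times, each cut chosen greedily to
    maximise the decrease in total within-cluster sum of squared
    deviations, with ties again broken by smallest edge id. Deterministic.
    """
    x = np.asarray(attrs, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    n = len(ids)
    if x.shape[0] != n:
        raise ValueError("attrs rows must match ids")
    if not 1 <= k <= n:
        raise ValueError(f"k={k} out of range 1..{n}")
    sd = x.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    xz = (x - x.mean(axis=0)) / sd

    pos = {c: i for i, c in enumerate(ids)}
    edges = []  # (weight, edge_id, u, v)
    eid = 0
    for u in ids:
        for v in sorted(adjacency.first_order.get(u, ())):
            if pos[v] <= pos[u]:
                continue
            d = float(((xz[pos[u]] - xz[pos[v]]) ** 2).sum())
            edges.append((d, eid, pos[u], pos[v]))
            eid += 1
    # Kruskal MST with (weight, edge id) ordering
    parent = list(range(n))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    mst: list[tuple[int, int, int]] = []  # (edge_id, u, v)
    for d, e, u, v in sorted(edges):
        ru, rv = find(u), find(v)
        if ru != rv:
            parent[ru] = rv
            mst.append((e, u, v))
    n_comp = n - len(mst)
    if k < n_comp:
        raise ValueError(
            f"contiguity graph has {n_comp} components; k must be ≥ {n_comp}"
        )

    # forest as adjacency lists over MST edges
    tree_adj: dict[int, set[tuple[int, int]]] = {i: set() for i in range(n)}
    for e, u, v in mst:
        tree_adj[u].add((v, e))
        tree_adj[v].add((u, e))

    def component(start: int, banned_edge: int | None) -> np.ndarray:
        seen = {start}
        stack = [start]
        while stack:
            a = stack.pop()
            for b, e in tree_adj[a]:
                if e == banned_edge or b in seen:
                    continue
                seen.add(b)
                stack.append(b)
        return np.fromiter(seen, dtype=np.int64)

    remaining = sorted(mst)  # by edge id
    for _ in range(k - n_comp):
        best = None  # (-decrease, edge_id, parts)
        for e, u, v in remaining:
            part_u = component(u, e)
            part_v = component(v, e)
            whole = np.concatenate([part_u, part_v])
            dec = _component_ss(xz, whole) - _component_ss(xz, part_u) - _component_ss(
                xz, part_v
            )
            cand = (-dec, e, (e, u, v))
            if best is None or cand < best:
                best = cand
        assert best is not None
        cut = best[2]
        remaining.remove(cut)
        tree_adj[cut[1]].discard((cut[2], cut[0]))
        tree_adj[cut[2]].discard((cut[1], cut[0]))

    labels = np.full(n, -1, dtype=np.int64)
    c = 0
    for i in range(n):
        if labels[i] == -1:
            comp = component(i, None)
            labels[comp] = c
            c += 1
    wss = sum(_component_ss(xz, np.where(labels == ci)[0]) for ci in range(c))
    return ClusterAssignment(list(ids), labels, c, float(wss))
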