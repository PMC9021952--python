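"""Weights, global/local Moran's I with permutation inference, and
SKATER regionalization."""

import itertools

import numpy as np
import pytest

from hextable import (
    build_weights,
    global_moran,
    local_moran,
    skater_cluster,
)
from hextable.context import AdjacencyMap
from hextable.spatial_stats import DegenerateVarianceError

from conftest import grid_adjacency, path_adjacency


class TestWeights:
    def test_path_row_standardized(self):
        w = build_weights(path_adjacency(3), standardize="row")
        rows = {w.ids[i]: dict(zip([w.ids[j] for j in w.neighbors[i]], w.weights[i]))
                for i in range(w.n)}
        assert rows == {
            "u0": {"u1": 1.0},
            "u1": {"u0": 0.5, "u2": 0.5},
            "u2": {"u1": 1.0},
        }

    def test_island_flagged(self):
        adj = AdjacencyMap({"a": {"b"}, "b": {"a"}, "c": set()},
                           {"a": set(), "b": set(), "c": set()})
        w = build_weights(adj)
        assert w.islands == ["c"]

    def test_binary_weights_symmetric_on_random_grid(self):
        w = build_weights(grid_adjacency(5, 4, queen=True), standardize="none")
        m = w.dense()
        assert np.array_equal(m, m.T)
        assert np.all(np.diag(m) == 0)

    def test_row_standardized_rows_sum_to_one(self):
        w = build_weights(grid_adjacency(4, 4), standardize="row")
        assert np.allclose(w.dense().sum(axis=1), 1.0)


class TestGlobalMoran:
    def test_path_123_is_zero(self):
        w = build_weights(path_adjacency(3))
        assert global_moran([1, 2, 3], w) == pytest.approx(0.0, abs=1e-12)

    def test_path4_1133_is_half(self):
        w = build_weights(path_adjacency(4))
        assert global_moran([1, 1, 3, 3], w) == pytest.approx(0.5)

    def test_checkerboard_is_minus_one(self):
        adj = grid_adjacency(4, 4, queen=False)
        w = build_weights(adj)
        vals = [1 if (int(c[1]) + int(c[3])) % 2 == 0 else -1 for c in w.ids]
        assert global_moran(vals, w) == pytest.approx(-1.0)

    def test_constant_input_degenerate(self):
        w = build_weights(path_adjacency(4))
        with pytest.raises(DegenerateVarianceError):
            global_moran([2, 2, 2, 2], w)

    @pytest.mark.parametrize("seed", range(10))
    def test_mean_local_equals_global(self, seed):
        rng = np.random.default_rng(seed)
        w = build_weights(grid_adjacency(6, 6, queen=True), standardize="row")
        x = rng.standard_normal(w.n)
        res = local_moran(x, w, n_perm=99, seed=seed)
        assert np.mean(res.local_i) == pytest.approx(global_moran(x, w), abs=1e-9)


class TestLocalMoran:
    def test_path_123_all_zero(self):
        w = build_weights(path_adjacency(3))
        res = local_moran([1, 2, 3], w, seed=0)
        assert np.allclose(res.local_i, 0.0, atol=1e-12)

    def test_path4_closed_form(self):
        w = build_weights(path_adjacency(4))
        res = local_moran([1, 1, 3, 3], w, seed=0)
        assert np.allclose(res.local_i, [1, 0, 0, 1], atol=1e-12)
        assert np.mean(res.local_i) == pytest.approx(0.5)

    def test_reproducible_under_seed(self):
        w = build_weights(grid_adjacency(5, 5))
        rng = np.random.default_rng(8)
        x = rng.standard_normal(w.n)
        a = local_moran(x, w, n_perm=199, seed=42)
        b = local_moran(x, w, n_perm=199, seed=42)
        assert np.array_equal(a.pseudo_p, b.pseudo_p)
        assert a.labels == b.labels

    def test_pseudo_p_bounds_and_label_consistency(self):
        w = build_weights(grid_adjacency(6, 6, queen=True))
        rng = np.random.default_rng(3)
        x = rng.standard_normal(w.n)
        res = local_moran(x, w, n_perm=199, seed=1)
        assert ((res.pseudo_p > 0) & (res.pseudo_p <= 1)).all()
        z = x - x.mean()
        lagz = w.lag(z)
        for i, lab in enumerate(res.labels):
            if lab == "NS":
                continue
            assert res.pseudo_p[i] <= res.alpha
            if lab in ("HH", "HL"):
                assert z[i] > 0
            else:
                assert z[i] < 0
            if lab in ("HH", "LH"):
                assert lagz[i] > 0
            else:
                assert lagz[i] < 0

    def test_hot_spot_detected_on_planted_block(self):
        w = build_weights(grid_adjacency(8, 8, queen=True))
        rng = np.random.default_rng(12)
        x = rng.standard_normal(w.n)
        hot = [i for i, c in enumerate(w.ids) if c in
               {"r3c3", "r3c4", "r4c3", "r4c4", "r3c5", "r4c5"}]
        x[hot] += 5.0
        res = local_moran(x, w, n_perm=499, seed=2)
        labels = np.array(res.labels)
        assert (labels[hot] == "HH").sum() >= 4

    def test_p_adjust_only_shrinks_significance(self):
        w = build_weights(grid_adjacency(8, 8, queen=True))
        rng = np.random.default_rng(17)
        x = rng.standard_normal(w.n)
        x[:6] += 4.0  # something to detect
        raw = local_moran(x, w, n_perm=199, seed=4)
        for method in ("bonferroni", "fdr_bh"):
            adj = local_moran(x, w, n_perm=199, seed=4, p_adjust=method)
            assert adj.significant().sum() <= raw.significant().sum()
            # adjusted labelling never invents significance
            for a, r in zip(adj.labels, raw.labels):
                assert a == "NS" or a == r

    def test_minimum_permutations_enforced(self):
        w = build_weights(path_adjacency(5))
        with pytest.raises(ValueError):
            local_moran([1, 2, 3, 4, 5], w, n_perm=10)

    def test_type_one_error_calibrated(self):
        """Under spatial randomness the significant fraction at α=0.05
        stays near α (quick 30-replicate version of the full check)."""
        w = build_weights(grid_adjacency(10, 10, queen=False))
        rng = np.random.default_rng(100)
        fracs = [
            np.mean(local_moran(rng.standard_normal(w.n), w,
                                n_perm=199, seed=r).significant())
            for r in range(30)
        ]
        mc_se = np.std(fracs, ddof=1) / np.sqrt(len(fracs))
        assert abs(np.mean(fracs) - 0.05) <= max(2 * mc_se, 0.02)


def exhaustive_best_2partition(adj: AdjacencyMap, ids, x):
    """Oracle: best contiguous 2-partition by within-cluster SS, found by
    enumerating all subsets and checking contiguity by traversal."""
    x = np.asarray(x, dtype=float)
    xz = (x - x.mean()) / x.std()

    def connected(sub):
        sub = set(sub)
        if not sub:
            return False
        seen = {next(iter(sub))}
        stack = list(seen)
        while stack:
            c = stack.pop()
            for nb in adj.first_order[c] & sub:
                if nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        return seen == sub

    def ss(sub):
        v = xz[[ids.index(c) for c in sub]]
        return ((v - v.mean()) ** 2).sum()

    best, best_ss = None, np.inf
    for r in range(1, len(ids)):
        for combo in itertools.combinations(ids, r):
            a = set(combo)
            b = set(ids) - a
            if connected(a) and connected(b):
                total = ss(a) + ss(b)
                if total < best_ss - 1e-12:
                    best, best_ss = (frozenset(a), frozenset(b)), total
    return best, best_ss


class TestSkater:
    def test_path4_recovers_halves_vs_exhaustive(self):
        adj = path_adjacency(4)
        ids = sorted(adj.first_order)
        x = [0.0, 0.0, 10.0, 10.0]
        got = skater_cluster(ids, np.array(x), adj, k=2)
        parts = {frozenset(got.members(0)), frozenset(got.members(1))}
        oracle, _ = exhaustive_best_2partition(adj, ids, x)
        assert parts == set(oracle)
        assert parts == {frozenset({"u0", "u1"}), frozenset({"u2", "u3"})}

    def test_k1_single_cluster_and_kn_singletons(self):
        adj = grid_adjacency(3, 3)
        ids = sorted(adj.first_order)
        x = np.arange(9.0)
        one = skater_cluster(ids, x, adj, k=1)
        assert one.k == 1 and len(set(one.labels)) == 1
        alln = skater_cluster(ids, x, adj, k=9)
        assert alln.k == 9 and alln.within_ss == pytest.approx(0.0)

    def test_clusters_always_contiguous(self):
        rng = np.random.default_rng(6)
        adj = grid_adjacency(5, 5, queen=False)
        ids = sorted(adj.first_order)
        x = rng.standard_normal((25, 3))
        for k in (2, 4, 7):
            got = skater_cluster(ids, x, adj, k=k)
            for c in range(got.k):
                members = set(got.members(c))
                seen = {next(iter(members))}
                stack = list(seen)
                while stack:
                    u = stack.pop()
                    for nb in adj.first_order[u] & members:
                        if nb not in seen:
                            seen.add(nb)
                            stack.append(nb)
                assert seen == members

    def test_within_ss_non_increasing_in_k(self):
        rng = np.random.default_rng(7)
        adj = grid_adjacency(4, 5, queen=False)
        ids = sorted(adj.first_order)
        x = rng.standard_normal((20, 2))
        prev = np.inf
        for k in range(1, 10):
            got = skater_cluster(ids, x, adj, k=k)
            assert got.within_ss <= prev + 1e-9
            prev = got.within_ss

    def test_deterministic(self):
        rng = np.random.default_rng(9)
        adj = grid_adjacency(4, 4)
        ids = sorted(adj.first_order)
        x = rng.standard_normal((16, 2))
        a = skater_cluster(ids, x, adj, k=4)
        b = skater_cluster(ids, x, adj, k=4)
        assert np.array_equal(a.labels, b.labels)

    def test_k_out_of_range(self):
        adj = path_adjacency(3)
        with pytest.raises(ValueError):
            skater_cluster(sorted(adj.first_order), np.zeros(3), adj, k=4)
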