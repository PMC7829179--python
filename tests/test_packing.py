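from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from morphospace import IntervalAssemblage, decompose, order_pairs
from morphospace.indices import hull_volume


def exhaustive_max_retained(points, ceiling, k=2):
    """Oracle: largest subset of rows whose hull volume fits the ceiling.

    Searches cardinalities from |E1| downward; exact but exponential, so
    only usable at small S.
    """
    n = points.shape[0]
    for size in range(n, 0, -1):
        for combo in combinations(range(n), size):
            v, _ = hull_volume(points[list(combo)][:, :k])
            if v <= ceiling:
                return size
    return 0


def assemblage(richness_list):
    out = []
    for i, s in enumerate(richness_list, start=1):
        lo = 0.0 if i == 1 else 400.0 + (i - 2) * 500.0
        up = 400.0 + (i - 1) * 500.0
        species = [f"s{i}_{j}" for j in range(s)]
        out.append(IntervalAssemblage(
            transect="T", index=i, lower=lo, upper=up, plot_ids=[],
            species=species, incidence=pd.DataFrame(columns=species),
        ))
    return out


class TestOrderPairs:
    def test_hump_shaped_walk(self):
        pairs = order_pairs(assemblage([10, 30, 50, 40, 20]))
        labels = [(p.e1.index, p.e2.index) for p in pairs if p.status == "ok"]
        assert labels == [(2, 1), (3, 2), (3, 4), (4, 5)]

    def test_monotone_richness(self):
        pairs = order_pairs(assemblage([5, 10, 15]))
        labels = [(p.e1.index, p.e2.index) for p in pairs if p.status == "ok"]
        assert labels == [(2, 1), (3, 2)]

    def test_equal_richness_pair_is_none(self):
        pairs = order_pairs(assemblage([8, 8]))
        assert len(pairs) == 1 and pairs[0].status == "none"

    def test_single_assemblage_rejected(self):
        with pytest.raises(ValueError):
            order_pairs(assemblage([5]))


SQUARE = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]])


class TestDecompose:
    def test_pure_packing(self):
        e1 = np.vstack([SQUARE, [[0.5, 0.5], [0.3, 0.4], [0.6, 0.2]]])
        r = decompose(e1, SQUARE, rng=1)
        assert (r.expansion, r.packing) == (0, 3)
        assert r.packing_pct == pytest.approx(100.0)

    def test_pure_expansion(self):
        tri = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
        far = tri + [[10.0, 10.0], [10.0, 10.0], [10.0, 10.0]]
        e1 = np.vstack([tri, far])
        r = decompose(e1, tri, rng=1, n_starts=10)
        assert (r.expansion, r.packing) == (3, 0)
        assert r.expansion_pct == pytest.approx(100.0)
        # exhaustive confirmation at this size
        v2, _ = hull_volume(tri)
        assert exhaustive_max_retained(e1, v2 * 1.01) == 3

    def test_mixed_case_matches_exhaustive_optimum(self):
        """Nested squares + center: the oracle finds 6 retainable species
        (thin collinear subsets reach exactly V2), so expansion 3, packing 2."""
        outer = (SQUARE - 0.5) * 2 + 0.5
        e1 = np.vstack([outer, SQUARE, [[0.5, 0.5]]])
        v2, _ = hull_volume(SQUARE)
        opt = exhaustive_max_retained(e1, v2 * 1.01)
        assert opt == 6
        r = decompose(e1, SQUARE, rng=1, n_starts=30)
        assert len(e1) - r.expansion == opt
        assert (r.expansion, r.packing) == (3, 2)

    def test_conservation_and_flags(self, rng):
        for _ in range(20):
            s1, s2 = int(rng.integers(6, 12)), int(rng.integers(4, 6))
            e1 = rng.normal(size=(s1, 2))
            e2 = rng.normal(size=(s2, 2))
            r = decompose(e1, e2, rng=rng, n_starts=5)
            assert r.expansion + r.packing == r.delta_s == s1 - s2
            assert r.volume_ratio <= 1.01 + 1e-9
            assert (r.packing < 0) == (r.status == "negative_packing")

    def test_greedy_near_exhaustive(self, rng):
        """Greedy within 1 retained species of the exact optimum."""
        for _ in range(25):
            s1 = int(rng.integers(7, 11))
            e1 = rng.normal(size=(s1, 2))
            e2 = rng.normal(size=(4, 2)) * 0.6
            try:
                r = decompose(e1, e2, rng=rng, n_starts=20)
            except ValueError:
                continue  # degenerate E2 hull
            v2, _ = hull_volume(e2)
            opt = exhaustive_max_retained(e1, v2 * 1.01)
            assert s1 - r.expansion >= opt - 1

    def test_scale_invariance(self, rng):
        e1 = rng.normal(size=(9, 2))
        e2 = rng.normal(size=(5, 2))
        r1 = decompose(e1, e2, rng=3, n_starts=10)
        r2 = decompose(10.0 * e1, 10.0 * e2, rng=3, n_starts=10)
        assert (r1.expansion, r1.packing) == (r2.expansion, r2.packing)

    def test_deterministic_given_seed(self, rng):
        e1 = rng.normal(size=(10, 2))
        e2 = rng.normal(size=(5, 2))
        a = decompose(e1, e2, rng=7, n_starts=10)
        b = decompose(e1, e2, rng=7, n_starts=10)
        assert (a.expansion, a.packing, a.volume_ratio) == \
               (b.expansion, b.packing, b.volume_ratio)

    def test_pure_packing_idempotence(self, rng):
        """Extra points strictly inside hull(E2) never count as expansion."""
        for _ in range(10):
            e2 = rng.normal(size=(6, 2))
            inner = e2.mean(axis=0) + 0.05 * rng.normal(size=(4, 2))
            r = decompose(np.vstack([e2, inner]), e2, rng=rng)
            assert r.expansion == 0 and r.packing == 4

    def test_degenerate_e2_rejected(self):
        line = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0]])
        with pytest.raises(ValueError, match="degenerate"):
            decompose(np.vstack([line, [[5.0, 0.0]]]), line)

    def test_wrong_order_rejected(self):
        with pytest.raises(ValueError, match="richer"):
            decompose(SQUARE[:3], SQUARE)
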