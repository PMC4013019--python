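"""Great-circle distances, Moran/Geary vs brute-force oracles, permutation tests."""

import itertools
import math

import numpy as np
import pytest

from ecogrs import InvalidArgumentError, UndefinedResultError
from ecogrs.spatial import (EARTH_RADIUS_KM, SpatialFrame, SpatialWeights,
                            build_weights, correlogram, gearys_c,
                            great_circle_km, morans_i, randomization_test)


# ---------------------------------------------------------------------------
# Brute-force O(n^2) oracles
# ---------------------------------------------------------------------------

def moran_oracle(x, w):
    n = len(x)
    xbar = sum(x) / n
    s0 = sum(w[i][j] for i in range(n) for j in range(n))
    num = sum(w[i][j] * (x[i] - xbar) * (x[j] - xbar)
              for i in range(n) for j in range(n))
    den = sum((xi - xbar) ** 2 for xi in x)
    return (n / s0) * num / den


def geary_oracle(x, w):
    n = len(x)
    xbar = sum(x) / n
    s0 = sum(w[i][j] for i in range(n) for j in range(n))
    num = sum(w[i][j] * (x[i] - x[j]) ** 2
              for i in range(n) for j in range(n))
    den = sum((xi - xbar) ** 2 for xi in x)
    return ((n - 1) / (2 * s0)) * num / den


def random_weights(rng, n):
    w = rng.uniform(0.1, 2.0, size=(n, n))
    w = (w + w.T) / 2
    np.fill_diagonal(w, 0.0)
    return w


class TestGreatCircle:
    def test_identical_points_zero(self):
        assert great_circle_km(48.0, 2.0, 48.0, 2.0) == 0.0

    def test_antipodal_closed_form(self):
        assert great_circle_km(0.0, 0.0, 0.0, 180.0) == pytest.approx(
            math.pi * EARTH_RADIUS_KM, abs=0.1)

    def test_equatorial_degree_arc(self):
        assert great_circle_km(0.0, 0.0, 0.0, 1.0) == pytest.approx(
            math.pi / 180 * EARTH_RADIUS_KM, abs=1e-3)

    def test_symmetry(self):
        a = great_circle_km(40.0, -3.0, 60.0, 25.0)
        b = great_circle_km(60.0, 25.0, 40.0, -3.0)
        assert a == pytest.approx(b, abs=1e-9)

    def test_invalid_coordinates_rejected(self):
        with pytest.raises(InvalidArgumentError):
            great_circle_km(91.0, 0.0, 0.0, 0.0)


class TestBuildWeights:
    def frame(self, n=5, seed=26):
        rng = np.random.default_rng(seed)
        return SpatialFrame(names=[f"p{i}" for i in range(n)],
                            lat=rng.uniform(35, 60, n),
                            lon=rng.uniform(-5, 30, n),
                            values=rng.normal(size=n))

    def test_equidistant_binary_all_ones(self):
        # three points on the equator, 10 degrees apart pairwise is not equal;
        # use threshold above the max distance instead
        f = self.frame(3)
        from ecogrs.spatial import pairwise_distances
        thr = pairwise_distances(f).max() + 1
        W = build_weights(f, scheme="binary", threshold=thr, row_standardize=False)
        off = ~np.eye(3, dtype=bool)
        assert np.all(W.matrix[off] == 1.0)

    def test_row_standardized_rows_sum_to_one(self):
        W = build_weights(self.frame(), scheme="inverse_distance")
        assert np.allclose(W.matrix.sum(axis=1), 1.0, atol=1e-12)

    def test_inverse_distance_homogeneity(self):
        f = self.frame()
        W = build_weights(f, row_standardize=False)
        from ecogrs.spatial import pairwise_distances
        d = pairwise_distances(f)
        off = ~np.eye(f.n, dtype=bool)
        assert np.allclose(W.matrix[off] * d[off], 1.0)

    def test_duplicate_coordinates_named(self):
        f = SpatialFrame(names=["a", "b", "c"], lat=[40, 40, 50],
                         lon=[3, 3, 3], values=[1.0, 2.0, 3.0])
        with pytest.raises(InvalidArgumentError, match="'a'.*'b'"):
            build_weights(f, scheme="inverse_distance")


class TestMoranGeary:
    def test_match_brute_force_oracles(self):
        rng = np.random.default_rng(27)
        for _ in range(25):
            n = 10
            x = rng.normal(size=n)
            w = random_weights(rng, n)
            W = SpatialWeights(matrix=w, scheme="custom")
            assert morans_i(x, W) == pytest.approx(
                moran_oracle(x.tolist(), w.tolist()), abs=1e-12)
            assert gearys_c(x, W) == pytest.approx(
                geary_oracle(x.tolist(), w.tolist()), abs=1e-12)

    def test_moran_affine_invariance(self):
        rng = np.random.default_rng(28)
        x = rng.normal(size=8)
        W = SpatialWeights(matrix=random_weights(rng, 8), scheme="custom")
        assert morans_i(3.0 * x - 7.0, W) == pytest.approx(morans_i(x, W), abs=1e-10)

    def test_two_point_anticorrelation(self):
        W = SpatialWeights(matrix=np.array([[0.0, 1.0], [1.0, 0.0]]), scheme="custom")
        assert morans_i(np.array([0.0, 1.0]), W) == pytest.approx(-1.0)

    def test_geary_shift_invariance(self):
        rng = np.random.default_rng(29)
        x = rng.normal(size=8)
        W = SpatialWeights(matrix=random_weights(rng, 8), scheme="custom")
        assert gearys_c(x + 11.0, W) == pytest.approx(gearys_c(x, W), abs=1e-10)

    def test_geary_zero_for_within_cluster_constant(self):
        # two far clusters, constant values within each, binary within-cluster
        # weights: all weighted differences vanish
        w = np.zeros((6, 6))
        for i, j in [(0, 1), (0, 2), (1, 2), (3, 4), (3, 5), (4, 5)]:
            w[i, j] = w[j, i] = 1.0
        W = SpatialWeights(matrix=w, scheme="custom")
        x = np.array([1.0, 1.0, 1.0, 4.0, 4.0, 4.0])
        assert gearys_c(x, W) == pytest.approx(0.0, abs=1e-15)

    def test_zero_variance_undefined(self):
        W = SpatialWeights(matrix=random_weights(np.random.default_rng(1), 5),
                           scheme="custom")
        with pytest.raises(UndefinedResultError):
            morans_i(np.ones(5), W)

    def test_row_standardization_preserves_moran_sign(self):
        rng = np.random.default_rng(30)
        for seed in range(10):
            f = SpatialFrame(names=[f"p{i}" for i in range(8)],
                             lat=rng.uniform(35, 60, 8),
                             lon=rng.uniform(-5, 30, 8),
                             values=rng.normal(size=8))
            Wr = build_weights(f, row_standardize=True)
            Wu = build_weights(f, row_standardize=False)
            a, b = morans_i(f.values, Wr), morans_i(f.values, Wu)
            if abs(a) > 1e-6 and abs(b) > 1e-6:
                assert np.sign(a) == np.sign(b)


class TestRandomizationTest:
    def frame(self, n, seed):
        rng = np.random.default_rng(seed)
        return SpatialFrame(names=[f"p{i}" for i in range(n)],
                            lat=rng.uniform(35, 60, n),
                            lon=rng.uniform(-5, 30, n),
                            values=rng.normal(size=n))

    def test_monte_carlo_matches_exhaustive_enumeration(self):
        # n=6: compare the Monte-Carlo p with the exact p over all 720
        # permutations, within 3 binomial SE at 9999 permutations
        f = self.frame(6, seed=31)
        W = build_weights(f)
        obs = morans_i(f.values, W)
        stats = [morans_i(np.array(perm), W)
                 for perm in itertools.permutations(f.values)]
        exact = np.mean([s >= obs - 1e-12 for s in stats])
        res = randomization_test("I", f.values, W, n_perm=9999, seed=5)
        se = np.sqrt(exact * (1 - exact) / 9999)
        assert abs(res.p - exact) < 3 * se + 1e-4

    def test_type_i_error_calibration(self):
        # iid values: one-sided Moran test at alpha=0.05 rejects ~5%
        rng = np.random.default_rng(32)
        rejections = 0
        n_rep = 400
        for _ in range(n_rep):
            f = SpatialFrame(names=[f"p{i}" for i in range(10)],
                             lat=rng.uniform(35, 60, 10),
                             lon=rng.uniform(-5, 30, 10),
                             values=rng.normal(size=10))
            W = build_weights(f)
            res = randomization_test("I", f.values, W, n_perm=199,
                                     seed=int(rng.integers(2 ** 31)))
            rejections += res.p <= 0.05
        rate = rejections / n_rep
        assert 0.05 - 3 * np.sqrt(0.05 * 0.95 / n_rep) <= rate \
            <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / n_rep)

    def test_pure_cline_attains_minimal_p(self):
        # monotone surface on a regular grid maximises I among permutations
        lat = np.repeat(np.linspace(36, 60, 4), 4)
        lon = np.tile(np.linspace(-5, 25, 4), 4)
        f = SpatialFrame(names=[f"p{i}" for i in range(16)], lat=lat,
                         lon=lon, values=lat)
        W = build_weights(f)
        res = randomization_test("I", f.values, W, n_perm=999, seed=6)
        assert res.p == pytest.approx(1 / 1000)

    def test_p_floor_and_reproducibility(self):
        f = self.frame(8, seed=34)
        W = build_weights(f)
        a = randomization_test("I", f.values, W, seed=9)
        b = randomization_test("I", f.values, W, seed=9)
        assert a.p == b.p
        assert a.p >= 1 / (a.n_perm + 1)

    def test_permutation_mean_near_theoretical(self):
        # E[I] under randomization = -1/(n-1)
        f = self.frame(9, seed=35)
        W = build_weights(f)
        res = randomization_test("I", f.values, W, n_perm=9999, seed=10)
        assert res.perm_mean == pytest.approx(-1 / 8, abs=0.02)

    def test_geary_default_alternative_less(self):
        f = self.frame(8, seed=36)
        W = build_weights(f)
        res = randomization_test("C", f.values, W, seed=11)
        assert res.alternative == "less"


class TestCorrelogram:
    def cline_frame(self, n, seed, noise=0.0):
        rng = np.random.default_rng(seed)
        lat = rng.uniform(35, 62, n)
        lon = rng.uniform(-8, 30, n)
        vals = lat + rng.normal(0, noise, n)
        return SpatialFrame(names=[f"p{i}" for i in range(n)], lat=lat,
                            lon=lon, values=vals)

    def test_pair_counts_partition(self):
        f = self.cline_frame(12, seed=37, noise=5.0)
        corr = correlogram(f, n_classes=6, n_perm=99, seed=1)
        assert corr.table.n_pairs.sum() == 12 * 11 // 2

    def test_cline_pattern_short_positive_long_negative(self):
        wins = 0
        for seed in range(10):
            f = self.cline_frame(15, seed=200 + seed, noise=2.0)
            corr = correlogram(f, n_classes=6, n_perm=99, seed=seed)
            t = corr.table
            wins += (t.moran_i.iloc[0] > 0) and (t.moran_i.iloc[-1] < 0)
        assert wins >= 9

    def test_iid_values_rarely_significant(self):
        clean = 0
        rng = np.random.default_rng(38)
        for seed in range(20):
            f = SpatialFrame(names=[f"p{i}" for i in range(12)],
                             lat=rng.uniform(35, 60, 12),
                             lon=rng.uniform(-5, 30, 12),
                             values=rng.normal(size=12))
            corr = correlogram(f, n_classes=6, n_perm=199, seed=seed)
            clean += not (corr.table.p_i < 0.05).any()
        assert clean >= 14  # >= 70% of seeds show no significant class

    def test_too_few_pairs_rejected(self):
        f = self.cline_frame(3, seed=39, noise=1.0)
        with pytest.raises(InvalidArgumentError):
            correlogram(f, n_classes=6, n_perm=99, seed=1)
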