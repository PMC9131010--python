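"""Weights construction, global/local Moran against naive oracles, inference."""

import itertools

import numpy as np
import pytest
from hypothesis import given, strategies as st

from streetstress.spatial import (
    LISA,
    Moran,
    SpatialWeights,
    build_weights,
    local_morans_i,
    manhattan_distance,
    min_neighbor_threshold,
    moran_scatter,
    neighbor_count_histogram,
)
from streetstress.synthetic import grid_points

from conftest import naive_global_moran, naive_local_moran


class TestDistanceAndThreshold:
    def test_manhattan_examples(self):
        assert manhattan_distance((0, 0), (3, 4)) == 7
        assert manhattan_distance((2, 5), (2, 5)) == 0

    def test_manhattan_symmetry(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a, b = rng.normal(size=(2, 2))
            assert manhattan_distance(a, b) == manhattan_distance(b, a)

    def test_collinear_0_1_6(self):
        pts = np.array([[0.0, 0], [1.0, 0], [6.0, 0]])
        assert min_neighbor_threshold(pts) == 5.0

    def test_two_points(self):
        assert min_neighbor_threshold(np.array([[0.0, 0], [0.0, 3.5]])) == 3.5

    def test_unit_grid(self):
        assert min_neighbor_threshold(grid_points(4, 4, 1.0)) == 1.0


class TestBuildWeights:
    def test_two_mutual_neighbors(self):
        w = build_weights(np.array([[0.0, 0], [1.0, 0]]), threshold=1.0)
        dense = w.matrix.toarray()
        np.testing.assert_allclose(dense, [[0, 1], [1, 0]])
        assert w.s0 == 2.0

    def test_collinear_auto_threshold(self):
        pts = np.array([[0.0, 0], [1.0, 0], [6.0, 0]])
        w = build_weights(pts, threshold="auto")
        assert w.threshold == 5.0
        # distances: d(0,1)=1, d(1,6)=5 (inclusive), d(0,6)=6 > 5
        assert list(w.neighbor_counts()) == [1, 2, 1]
        np.testing.assert_allclose(w.matrix.sum(axis=1).ravel(), 1.0)

    def test_band_inclusive_at_threshold(self):
        w = build_weights(np.array([[0.0, 0], [5.0, 0]]), threshold=5.0)
        assert w.neighbor_counts().sum() == 2

    def test_all_isolated_is_error(self):
        with pytest.raises(ValueError, match="isolated"):
            build_weights(np.array([[0.0, 0], [10.0, 0]]), threshold=1.0)

    def test_partial_isolates_warn(self):
        pts = np.array([[0.0, 0], [1.0, 0], [50.0, 0]])
        with pytest.warns(UserWarning, match="no neighbor"):
            w = build_weights(pts, threshold=2.0)
        assert list(w.isolates) == [2]

    def test_neighbor_relation_symmetric_before_standardization(self, weights100):
        b = weights100.binary
        assert (b != b.T).nnz == 0


class TestNeighborHistogram:
    def test_two_mutual(self):
        w = build_weights(np.array([[0.0, 0], [1.0, 0]]), threshold=1.0)
        assert neighbor_count_histogram(w) == {1: 2}

    def test_collinear_fixture(self):
        pts = np.array([[0.0, 0], [1.0, 0], [6.0, 0]])
        hist = neighbor_count_histogram(build_weights(pts))
        assert hist == {1: 2, 2: 1}

    def test_partition_sums_to_n(self, weights100):
        assert sum(neighbor_count_histogram(weights100).values()) == weights100.n


class TestGlobalMoran:
    def test_checkerboard_is_perfect_dispersion(self, checkerboard):
        values, w = checkerboard
        m = Moran(values, w)
        assert m.I == pytest.approx(-1.0)
        assert m.E_I == pytest.approx(-1 / 3)

    def test_matches_naive_double_loop(self):
        rng = np.random.default_rng(42)
        for n in (5, 17, 50):
            pts = rng.uniform(0, 100, size=(n, 2))
            w = build_weights(pts, threshold="auto")
            x = rng.normal(50, 10, n)
            assert Moran(x, w).I == pytest.approx(
                naive_global_moran(x, w.matrix.toarray()), abs=1e-12
            )

    def test_constant_values_error(self, weights100):
        with pytest.raises(ValueError, match="constant"):
            Moran(np.full(weights100.n, 5.0), weights100)

    def test_normality_and_permutation_variance_agree_roughly(self, weights100):
        rng = np.random.default_rng(1)
        x = rng.normal(size=weights100.n)
        rand = Moran(x, weights100, variance="randomization")
        norm_ = Moran(x, weights100, variance="normality")
        perm = Moran(x, weights100, variance="permutation", n_perm=999, seed=5)
        assert rand.VAR_I == pytest.approx(norm_.VAR_I, rel=0.2)
        assert rand.VAR_I == pytest.approx(perm.VAR_I, rel=0.35)

    def test_sar_fields_detected_null_fields_centered(self, weights100, grid100):
        from streetstress.synthetic import generate_latent_stress, generate_scene_compositions

        comp = generate_scene_compositions(grid100, seed=0)
        flat = np.zeros(19)
        hits = 0
        null_i = []
        for rep in range(20):
            hi = generate_latent_stress(comp, flat, 50, 0.7, 5.0, weights100, seed=100 + rep)
            lo = generate_latent_stress(comp, flat, 50, 0.0, 5.0, weights100, seed=100 + rep)
            m = Moran(hi, weights100)
            hits += (m.I > 0) and (m.p < 0.05)
            null_i.append(Moran(lo, weights100).I)
        assert hits >= 18
        assert abs(np.mean(null_i) - (-1 / (weights100.n - 1))) < 0.05


class TestMoranScatter:
    def test_checkerboard_slope_is_minus_one(self, checkerboard):
        values, w = checkerboard
        z, lag = moran_scatter(values, w)
        slope = np.polyfit(z, lag, 1)[0]
        assert slope == pytest.approx(-1.0)

    def test_slope_equals_global_i_on_random_fixtures(self, weights100):
        rng = np.random.default_rng(3)
        for _ in range(5):
            x = rng.normal(50, 8, weights100.n)
            z, lag = moran_scatter(x, weights100)
            slope = np.polyfit(z, lag, 1)[0]
            assert abs(slope - Moran(x, weights100).I) < 1e-9

    def test_scatter_quadrants_match_lisa_quadrants_pre_significance(self, weights100):
        rng = np.random.default_rng(4)
        x = rng.normal(50, 8, weights100.n)
        z, lag = moran_scatter(x, weights100)
        lisa = LISA(x, weights100, n_perm=99, alpha=1.1, seed=0)  # alpha>1: all significant
        expected = np.where(z > 0, np.where(lag > 0, "HH", "HL"),
                            np.where(lag > 0, "LH", "LL"))
        assert (lisa.quadrant == expected).all()


class TestLISA:
    def test_checkerboard_locals_all_minus_one(self, checkerboard):
        values, w = checkerboard
        lisa = LISA(values, w, n_perm=99, seed=0)
        np.testing.assert_allclose(lisa.Ii, -1.0)
        assert lisa.Ii.sum() == pytest.approx(w.s0 * Moran(values, w).I)

    def test_matches_naive_double_loop(self):
        rng = np.random.default_rng(7)
        pts = rng.uniform(0, 100, size=(30, 2))
        w = build_weights(pts, threshold="auto")
        x = rng.normal(40, 12, 30)
        np.testing.assert_allclose(
            LISA(x, w, n_perm=9, seed=0).Ii,
            naive_local_moran(x, w.matrix.toarray()),
            atol=1e-10,
        )

    def test_sum_identity_on_random_fixtures(self, weights100):
        rng = np.random.default_rng(8)
        for _ in range(5):
            x = rng.normal(50, 10, weights100.n)
            lisa = LISA(x, weights100, n_perm=9, seed=0)
            assert lisa.Ii.sum() == pytest.approx(
                weights100.s0 * Moran(x, weights100).I, abs=1e-9
            )

    @given(st.integers(0, 10_000))
    def test_sum_identity_property(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.uniform(0, 50, size=(12, 2))
        w = build_weights(pts, threshold="auto")
        x = rng.normal(size=12)
        lisa = LISA(x, w, n_perm=9, seed=0)
        assert lisa.Ii.sum() == pytest.approx(w.s0 * Moran(x, w).I, abs=1e-9)

    def test_conditional_permutation_matches_exhaustive_oracle(self):
        # n = 6 chain: exhaustive conditional null enumerates all 5!
        # arrangements of the other five values; the sampled pseudo p must
        # sit within binomial error of the exact tail probability.
        pts = np.array([[0.0, 0], [1.0, 0], [2.0, 0], [3.0, 0], [4.0, 0], [5.0, 0]])
        w = build_weights(pts, threshold=1.0)
        x = np.array([10.0, 30.0, 12.0, 45.0, 8.0, 25.0])
        lisa = LISA(x, w, n_perm=999, seed=1)
        d = x - x.mean()
        s2 = (d**2).sum() / 6
        dense = w.matrix.toarray()
        for i in range(6):
            others = np.delete(d, i)
            nbrs = np.flatnonzero(dense[i])
            stats = []
            for perm in itertools.permutations(others):
                arranged = np.asarray(perm)
                full = np.insert(arranged, i, d[i])
                stats.append(d[i] / s2 * (dense[i] @ full))
            stats = np.asarray(stats)
            exact = (np.abs(stats) >= abs(lisa.Ii[i]) - 1e-12).mean()
            tol = 4 * np.sqrt(max(exact * (1 - exact), 0.01) / 999) + 1 / 999
            assert abs(lisa.p[i] - exact) < max(tol, 0.075)

    def test_quadrant_definition(self, weights100):
        rng = np.random.default_rng(9)
        x = rng.normal(50, 10, weights100.n)
        lisa = LISA(x, weights100, n_perm=199, seed=2)
        sig = lisa.p < lisa.alpha
        hh = sig & (lisa.z_value > 0) & (lisa.lag_z > 0)
        assert (lisa.quadrant[hh] == "HH").all()
        assert (lisa.quadrant[~sig] == "ns").all()
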