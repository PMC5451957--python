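"""Moran's I identities, permutation inference, and KDE surfaces."""

import numpy as np
import pytest

from profilemix import spatial


def brute_force_global_moran(values, W):
    """Independent double-loop implementation of the global statistic."""
    z = np.asarray(values, dtype=float) - np.mean(values)
    n = z.size
    num = 0.0
    s0 = 0.0
    for i in range(n):
        for j in range(n):
            num += W[i, j] * z[i] * z[j]
            s0 += W[i, j]
    return n / s0 * num / (z * z).sum()


def brute_force_local_moran(values, W):
    z = np.asarray(values, dtype=float) - np.mean(values)
    n = z.size
    m2 = (z * z).sum() / n
    out = np.zeros(n)
    for i in range(n):
        for j in range(n):
            out[i] += W[i, j] * z[j]
        out[i] *= z[i] / m2
    return out


class TestWeights:
    def test_knn_has_no_islands_and_zero_diagonal(self, rng):
        pts = rng.uniform(0, 10, size=(30, 2))
        W = spatial.knn_weights(pts, k=4)
        assert W.islands().size == 0
        assert np.all(np.diag(W.W) == 0)
        assert np.allclose(W.W.sum(axis=1), 1.0)  # row-standardised

    def test_distance_band_islands_detected(self, rng):
        pts = np.vstack([rng.uniform(0, 1, size=(10, 2)), [[100.0, 100.0]]])
        W = spatial.distance_band_weights(pts, band_m=5.0)
        assert 10 in W.islands()
        v = rng.normal(size=11)
        with pytest.raises(ValueError, match="islands.*10"):
            spatial.global_morans_i(v, W, n_perm=9, seed=0)

    def test_rook_grid_degree(self):
        W = spatial.rook_grid_weights((3, 3), row_standardize=False)
        deg = W.W.sum(axis=1)
        assert sorted(deg) == [2, 2, 2, 2, 3, 3, 3, 3, 4]


class TestGlobalMoran:
    def test_expected_value_closed_form(self, rng):
        pts = rng.uniform(0, 1, size=(255, 2))
        W = spatial.knn_weights(pts, k=8)
        res = spatial.global_morans_i(rng.normal(size=255), W, n_perm=9, seed=0)
        assert res["expected_I"] == pytest.approx(-1.0 / 254)

    def test_checkerboard_is_negatively_autocorrelated(self):
        W = spatial.rook_grid_weights((4, 4))
        vals = np.array([(ix + iy) % 2 for ix in range(4) for iy in range(4)], float)
        res = spatial.global_morans_i(vals, W, n_perm=199, seed=1)
        assert res["I"] == pytest.approx(
            brute_force_global_moran(vals, W.W), abs=1e-12
        )
        assert res["I"] < res["expected_I"]

    def test_agrees_with_brute_force_on_random_fixtures(self, rng):
        for _ in range(5):
            pts = rng.uniform(0, 1, size=(25, 2))
            W = spatial.knn_weights(pts, k=4)
            v = rng.normal(size=25)
            res = spatial.global_morans_i(v, W, n_perm=9, seed=0)
            assert res["I"] == pytest.approx(
                brute_force_global_moran(v, W.W), abs=1e-12
            )

    def test_affine_invariance_of_statistic(self, rng):
        pts = rng.uniform(0, 1, size=(40, 2))
        W = spatial.knn_weights(pts, k=5)
        v = rng.normal(size=40)
        i1 = spatial.global_morans_i(v, W, n_perm=9, seed=0)["I"]
        i2 = spatial.global_morans_i(3.0 * v + 7.0, W, n_perm=9, seed=0)["I"]
        assert i1 == pytest.approx(i2, abs=1e-12)

    def test_constant_values_rejected(self, rng):
        pts = rng.uniform(0, 1, size=(10, 2))
        W = spatial.knn_weights(pts, k=3)
        with pytest.raises(ValueError, match="constant"):
            spatial.global_morans_i(np.ones(10), W, n_perm=9, seed=0)

    def test_permutation_p_reproducible_under_seed(self, rng):
        pts = rng.uniform(0, 1, size=(30, 2))
        W = spatial.knn_weights(pts, k=4)
        v = rng.normal(size=30)
        p1 = spatial.global_morans_i(v, W, n_perm=199, seed=7)["p_value"]
        p2 = spatial.global_morans_i(v, W, n_perm=199, seed=7)["p_value"]
        assert p1 == p2


class TestLocalMoran:
    def test_sum_identity_with_global(self, rng):
        for _ in range(3):
            pts = rng.uniform(0, 1, size=(35, 2))
            W = spatial.knn_weights(pts, k=5)
            v = rng.normal(size=35)
            loc = spatial.local_morans_i(v, W, n_perm=9, seed=0)
            g = spatial.global_morans_i(v, W, n_perm=9, seed=0)
            assert loc["I_local"].sum() == pytest.approx(W.s0 * g["I"], abs=1e-10)

    def test_extreme_point_with_opposite_neighbours_is_negative(self):
        # centre point high, rook neighbours low
        W = spatial.rook_grid_weights((3, 3))
        v = np.zeros(9)
        v[4] = 10.0
        loc = spatial.local_morans_i(v, W, n_perm=19, seed=0)
        assert loc["I_local"][4] < 0

    def test_matches_brute_force(self, rng):
        pts = rng.uniform(0, 1, size=(20, 2))
        W = spatial.knn_weights(pts, k=4)
        v = rng.normal(size=20)
        loc = spatial.local_morans_i(v, W, n_perm=9, seed=0)
        assert np.allclose(loc["I_local"], brute_force_local_moran(v, W.W), atol=1e-12)

    def test_bh_adjustment_flag(self, rng):
        pts = rng.uniform(0, 1, size=(15, 2))
        W = spatial.knn_weights(pts, k=3)
        loc = spatial.local_morans_i(rng.normal(size=15), W, n_perm=19, seed=0, bh_adjust=True)
        assert (loc["p_bh"] >= loc["p_value"] - 1e-12).all()


class TestKDE:
    def test_single_point_peaks_at_nearest_node(self):
        dens, xs, ys = spatial.kde_surface(np.array([[500.0, 300.0]]), 100.0, (51, 51))
        i, j = np.unravel_index(np.argmax(dens), dens.shape)
        assert abs(xs[i] - 500.0) <= (xs[1] - xs[0])
        assert abs(ys[j] - 300.0) <= (ys[1] - ys[0])

    def test_two_distant_points_give_two_equal_modes(self):
        pts = np.array([[0.0, 0.0], [5000.0, 0.0]])
        dens, xs, ys = spatial.kde_surface(pts, 200.0, (101, 41))
        half = dens[: len(xs) // 2, :]
        other = dens[len(xs) // 2 :, :]
        assert half.max() == pytest.approx(other.max(), rel=1e-6)

    def test_integrates_to_one_on_padded_grid(self, rng):
        pts = rng.uniform(0, 2000, size=(40, 2))
        dens, xs, ys = spatial.kde_surface(pts, 300.0, (120, 120))
        integral = np.trapezoid(np.trapezoid(dens, ys, axis=1), xs)
        assert integral == pytest.approx(1.0, abs=0.02)

    def test_zero_bandwidth_rejected(self):
        with pytest.raises(ValueError, match="bandwidth"):
            spatial.kde_surface(np.array([[0.0, 0.0]]), 0.0)
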