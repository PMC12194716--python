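import numpy as np
import pytest

import _oracle
from cassfcm.dataset import MetricSpec, image_to_dataset
from cassfcm.engine import (CentroidSet, SmoothingConfig, forgy_init,
                            image_difference, init_sensitivity_experiment,
                            membership_matrix, run_cas_sfcm, update_centroids,
                            update_memberships)
from cassfcm.image import CIELAB, RasterImage
from cassfcm.reconstruction import reconstruct_image


def lab_image(values):
    return RasterImage(np.asarray(values, float), CIELAB)


class TestForgyInit:
    def test_r_equal_to_dataset_size_exhausts_instances(self, lab8):
        ds = image_to_dataset(lab8)
        C = forgy_init(ds, ds.n_instances, seed=3)
        assert np.array_equal(np.sort(C.points, axis=0), np.sort(ds.X, axis=0))

    def test_same_seed_same_selection(self, lab8):
        ds = image_to_dataset(lab8)
        a = forgy_init(ds, 4, seed=11)
        b = forgy_init(ds, 4, seed=11)
        assert np.array_equal(a.points, b.points)

    def test_centroids_are_distinct_dataset_rows(self, rng):
        img = lab_image(rng.uniform(0, 100, (2, 5, 3)))
        ds = image_to_dataset(img)
        C = forgy_init(ds, 3, seed=0)
        rows = {tuple(x) for x in ds.X}
        picked = [tuple(c) for c in C.points]
        assert len(set(picked)) == 3
        assert all(p in rows for p in picked)

    @pytest.mark.parametrize("r", [0, 11])
    def test_out_of_range_r_rejected(self, rng, r):
        ds = image_to_dataset(lab_image(rng.uniform(0, 100, (2, 5, 3))))
        with pytest.raises(ValueError):
            forgy_init(ds, r, seed=0)


class TestMemberships:
    def test_equidistant_pixel_splits_evenly(self):
        X = np.array([[0.5, 0.5, 50.0]])
        C = np.array([[0.0, 0.5, 40.0], [1.0, 0.5, 60.0]])
        U = membership_matrix(X, C, MetricSpec(alpha=0.5), m=2.0)
        assert np.allclose(U, [[0.5, 0.5]])

    def test_pixel_on_centroid_gets_full_membership(self):
        X = np.array([[0.0, 0.0, 10.0]])
        C = np.array([[0.0, 0.0, 10.0], [0.5, 0.5, 40.0], [1, 1, 80.0]])
        U = membership_matrix(X, C, MetricSpec(alpha=0.5), m=2.0)
        assert np.allclose(U, [[1.0, 0.0, 0.0]])

    def test_m2_distances_one_and_two(self):
        # distances (1, 2) with m=2 -> (0.8, 0.2)
        X = np.array([[0.0, 0.0, 0.0]])
        C = np.array([[0.0, 0.0, 1.0], [0.0, 0.0, -2.0]])
        U = membership_matrix(X, C, MetricSpec(alpha=1.0), m=2.0)
        assert np.allclose(U, [[0.8, 0.2]])

    def test_ruspini_partition_on_random_data(self, rng):
        X = rng.uniform(-30, 30, (200, 5))
        C = rng.uniform(-30, 30, (4, 5))
        for m in (1.5, 2.0, 3.0):
            U = membership_matrix(X, C, MetricSpec(alpha=0.6), m=m)
            assert np.allclose(U.sum(axis=1), 1.0, atol=1e-12)
            assert U.min() >= 0 and U.max() <= 1


class TestCentroids:
    def test_single_cluster_is_dataset_mean(self, lab8):
        ds = image_to_dataset(lab8)
        U = update_memberships(ds, forgy_init(ds, 1, 0), MetricSpec(), 2.0)
        C = update_centroids(ds, U, 2.0)
        assert np.allclose(C.points[0], ds.X.mean(axis=0), atol=1e-12)

    def test_crisp_point_masses_reproduce_points(self):
        img = lab_image([[[0.0], [100.0]]])
        ds = image_to_dataset(img)
        U = update_memberships(
            ds, CentroidSet(ds.X.copy()), MetricSpec(alpha=1.0), 2.0)
        C = update_centroids(ds, U, 2.0)
        assert np.allclose(np.sort(C.points[:, 2]), [0.0, 100.0])

    def test_matches_double_loop_oracle(self, lab8, rng):
        ds = image_to_dataset(lab8)
        U_raw = rng.random((64, 3))
        U_raw /= U_raw.sum(axis=1, keepdims=True)
        from cassfcm.engine import centroid_matrix
        ours = centroid_matrix(ds.X, U_raw, 2.0)
        ref = _oracle.centroids(ds.X, U_raw, 2.0)
        assert np.allclose(ours, ref, atol=1e-10)

    def test_centroids_stay_in_componentwise_hull(self, lab8):
        ds = image_to_dataset(lab8)
        C = forgy_init(ds, 4, seed=1)
        spec = MetricSpec(alpha=0.5)
        for _ in range(5):
            U = update_memberships(ds, C, spec, 2.0)
            C = update_centroids(ds, U, 2.0)
            assert np.all(C.points >= ds.X.min(axis=0) - 1e-9)
            assert np.all(C.points <= ds.X.max(axis=0) + 1e-9)

    def test_empty_cluster_is_reseeded_from_an_instance(self, lab8):
        ds = image_to_dataset(lab8)
        U = np.zeros((64, 2))
        U[:, 0] = 1.0  # cluster 1 holds no mass at all
        from cassfcm.engine import centroid_matrix
        C = centroid_matrix(ds.X, U, 2.0, np.random.default_rng(0))
        rows = {tuple(x) for x in ds.X}
        assert tuple(C[1]) in rows


class TestImageDifference:
    def test_identical_images_give_zero(self, lab8):
        assert image_difference(lab8, lab8) == 0.0

    def test_single_pixel_difference_averages(self):
        A = lab_image(np.zeros((10, 10, 3)))
        B_vals = np.zeros((10, 10, 3))
        B_vals[4, 7] = [6.0, 8.0, 0.0]  # tonal distance 10 at one pixel
        B = lab_image(B_vals)
        assert image_difference(A, B) == pytest.approx(0.1)
        assert image_difference(B, A) == pytest.approx(0.1)

    def test_matches_explicit_per_pixel_sum(self, rng):
        A = lab_image(rng.uniform(0, 100, (5, 6, 3)))
        B = lab_image(rng.uniform(0, 100, (5, 6, 3)))
        acc = 0.0
        for i in range(5):
            for j in range(6):
                acc += np.linalg.norm(A.values[i, j] - B.values[i, j])
        assert image_difference(A, B) == pytest.approx(acc / 30)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            image_difference(lab_image(np.zeros((2, 2, 3))),
                             lab_image(np.zeros((3, 2, 3))))


class TestFullIterationOracle:
    @pytest.mark.parametrize("r", [2, 3])
    @pytest.mark.parametrize("alpha", [0.0, 0.5, 1.0])
    def test_one_iteration_matches_loops(self, rng, r, alpha):
        # random 8x8 CIELab image
        lab = np.empty((8, 8, 3))
        lab[:, :, 0] = rng.uniform(0, 100, (8, 8))
        lab[:, :, 1:] = rng.uniform(-60, 60, (8, 8, 2))
        img = lab_image(lab)
        ds = image_to_dataset(img)
        spec = MetricSpec(alpha=alpha)
        C0 = forgy_init(ds, r, seed=7)
        U0 = update_memberships(ds, C0, spec, 2.0)
        # package path
        C1 = update_centroids(ds, U0, 2.0)
        U1 = update_memberships(ds, C1, spec, 2.0)
        I1 = reconstruct_image(U1.flat, C1.tonal, ds.grid_shape)
        # loop path
        C_ref, U_ref, I_ref = _oracle.one_iteration(
            ds.X, U0.flat, alpha, 2.0, ds.grid_shape, 3)
        assert np.allclose(C1.points, C_ref, atol=1e-10)
        assert np.allclose(U1.flat, U_ref, atol=1e-10)
        assert np.allclose(I1.values, I_ref, atol=1e-10)


class TestRun:
    def test_constant_image_single_cluster_is_identity(self):
        img = lab_image(np.tile([42.0, 5.0, -7.0], (6, 6, 1)))
        trace = run_cas_sfcm(img, SmoothingConfig(r=1, seed=0))
        assert trace.termination == "converged"
        for im in trace.images:
            assert np.allclose(im.values, img.values, atol=1e-6)

    def test_r1_converges_to_tonal_mean(self, lab8):
        trace = run_cas_sfcm(lab8, SmoothingConfig(r=1, alpha=0.5, seed=4))
        ds = image_to_dataset(lab8)
        final = trace.final_image.values
        assert np.allclose(final, ds.tonal.mean(axis=0), atol=1e-6)
        assert np.ptp(final.reshape(-1, 3), axis=0).max() < 1e-9  # flat

    def test_constant_image_is_fixed_point_for_any_r(self):
        img = lab_image(np.tile([60.0, -10.0, 20.0], (8, 8, 1)))
        for r in (2, 4):
            trace = run_cas_sfcm(img, SmoothingConfig(r=r, seed=1))
            assert np.allclose(trace.final_image.values, img.values,
                               atol=1e-9)

    def test_half_black_half_white_recovers_region_means(self):
        vals = np.zeros((16, 16, 3))
        vals[:, 8:, 0] = 100.0
        img = lab_image(vals)
        ds = image_to_dataset(img)
        # start from one instance per half, then iterate both the
        # engine and the double-loop oracle to convergence
        C = CentroidSet(np.vstack([ds.X[0], ds.X[15]]))
        spec = MetricSpec(alpha=1.0)
        for _ in range(20):
            U = update_memberships(ds, C, spec, 2.0)
            C = update_centroids(ds, U, 2.0)
        U_ref = _oracle.memberships(ds.X, C.points, 1.0, 2.0)
        assert np.allclose(U.flat, U_ref, atol=1e-10)
        out = reconstruct_image(U.flat, C.tonal, ds.grid_shape).values
        assert np.allclose(out[:, :8, 0], 0.0, atol=1e-6)
        assert np.allclose(out[:, 8:, 0], 100.0, atol=1e-6)

    def test_bit_identical_trace_for_same_seed(self, blob_fixture):
        img, _ = blob_fixture
        cfg = SmoothingConfig(r=2, alpha=0.5, max_iter=5, delta=1e-9, seed=9)
        a = run_cas_sfcm(img, cfg)
        b = run_cas_sfcm(img, cfg)
        assert a.diffs == b.diffs
        assert np.array_equal(a.final_image.values, b.final_image.values)

    def test_alpha1_is_equivariant_under_pixel_permutation(self, rng):
        lab = np.empty((6, 6, 3))
        lab[:, :, 0] = rng.uniform(0, 100, (6, 6))
        lab[:, :, 1:] = rng.uniform(-50, 50, (6, 6, 2))
        img = lab_image(lab)
        perm = rng.permutation(36)
        img_p = lab_image(lab.reshape(36, 3)[perm].reshape(6, 6, 3))

        spec = MetricSpec(alpha=1.0)
        ds, ds_p = image_to_dataset(img), image_to_dataset(img_p)
        # matching initializations: same tonal parts in both runs
        rows = np.array([0, 17, 30])
        inv = np.argsort(perm)
        C = CentroidSet(ds.X[rows])
        C_p = CentroidSet(ds_p.X[inv[rows]])
        for _ in range(10):
            U = update_memberships(ds, C, spec, 2.0)
            C = update_centroids(ds, U, 2.0)
            U_p = update_memberships(ds_p, C_p, spec, 2.0)
            C_p = update_centroids(ds_p, U_p, 2.0)
        out = reconstruct_image(U.flat, C.tonal, (6, 6)).values.reshape(36, 3)
        out_p = reconstruct_image(
            U_p.flat, C_p.tonal, (6, 6)).values.reshape(36, 3)
        # the permuted run's output is the permutation of the original's,
        # so the output tone multiset is permutation-invariant
        assert np.allclose(out_p, out[perm], atol=1e-8)

    def test_two_region_fixture_converges_non_trivially(self, blob_fixture):
        img, _ = blob_fixture
        trace = run_cas_sfcm(img, SmoothingConfig(r=2, alpha=0.5, seed=0))
        tones = trace.final_image.values.reshape(-1, 3)
        spread = np.linalg.norm(tones.max(axis=0) - tones.min(axis=0))
        assert spread > 5.0  # not flat: region contrast survives

    def test_ruspini_deviation_recorded_and_tiny(self, lab8):
        trace = run_cas_sfcm(lab8, SmoothingConfig(
            r=3, alpha=0.5, delta=1e-9, max_iter=20, seed=2))
        assert len(trace.ruspini_deviations) == len(trace.images)
        assert max(trace.ruspini_deviations) < 1e-9


class TestInitSensitivity:
    def test_table_shape_and_monotone_trend(self, rng):
        vals = np.zeros((24, 24, 3))
        vals[:, 12:, 0] = 60.0
        vals += rng.normal(0, 0.5, vals.shape)
        img = lab_image(vals)
        cfg = SmoothingConfig(r=2, alpha=1.0, seed=0)
        table = init_sensitivity_experiment(img, cfg, n_seeds=4, n_iters=12)
        assert list(table.columns) == ["iteration", "max_phi", "mean_phi"]
        assert len(table) == 13
        assert (table.mean_phi <= table.max_phi + 1e-12).all()
        assert table.max_phi.iloc[-1] <= table.max_phi.iloc[1] + 1e-12

    def test_requires_two_seeds(self, lab8):
        with pytest.raises(ValueError):
            init_sensitivity_experiment(
                lab8, SmoothingConfig(r=2), n_seeds=1, n_iters=2)
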