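import numpy as np
import pytest

from mritumor import (
    GrayImage,
    SegmentationConfig,
    extract_tumor_mask,
    kmeans_baseline,
    segment,
)
from mritumor.segmentation import (
    build_init_context,
    spatial_regularize,
    update_centroids,
    update_membership,
    weighted_objective,
)
from conftest import as_gray
from oracles import fcm_reference, lloyd_reference


class TestMembershipUpdate:
    def test_pixel_at_centroid_is_crisp(self):
        s = update_membership(np.array([0.0]), np.array([0.0, 10.0]), m=2.0)
        np.testing.assert_array_equal(s[:, 0], [1.0, 0.0])

    def test_equidistant_pixel_splits_evenly(self):
        for m in (1.5, 2.0, 3.0):
            s = update_membership(np.array([5.0]), np.array([0.0, 10.0]), m=m)
            np.testing.assert_allclose(s[:, 0], [0.5, 0.5])

    def test_hand_value(self):
        # d = (2, 8): s_0 = 1 / (1 + (2/8)^2) for m = 2
        s = update_membership(np.array([2.0]), np.array([0.0, 10.0]), m=2.0)
        np.testing.assert_allclose(s[:, 0], [0.9412, 0.0588], atol=1e-3)

    def test_coincident_centroids_split_equally(self):
        s = update_membership(np.array([3.0]), np.array([3.0, 3.0]), m=2.0)
        np.testing.assert_allclose(s[:, 0], [0.5, 0.5])

    def test_columns_sum_to_one(self, rng):
        x = rng.random(50)
        s = update_membership(x, np.array([0.1, 0.5, 0.9]), m=2.0)
        np.testing.assert_allclose(s.sum(axis=0), 1.0, atol=1e-9)


class TestCentroidUpdate:
    def test_crisp_membership_gives_cluster_means(self):
        x = np.array([0.0, 0.0, 10.0, 10.0])
        s = np.array([[1.0, 1.0, 0.0, 0.0], [0.0, 0.0, 1.0, 1.0]])
        np.testing.assert_allclose(update_centroids(x, s, 2.0), [0.0, 10.0])

    def test_uniform_membership_gives_data_mean(self):
        x = np.array([1.0, 2.0, 3.0, 6.0])
        s = np.full((2, 4), 0.5)
        np.testing.assert_allclose(update_centroids(x, s, 2.0), [x.mean()] * 2)

    def test_matches_direct_formula(self):
        x = np.array([0.0, 0.0, 0.0, 10.0, 10.0, 10.0])
        s = update_membership(x, np.array([1.0, 9.0]), m=2.0)
        T = update_centroids(x, s, 2.0)
        for k in range(2):
            expected = np.sum(s[k] ** 2 * x) / np.sum(s[k] ** 2)
            assert T[k] == pytest.approx(expected, abs=1e-12)

    def test_dead_cluster_keeps_previous_centroid(self):
        x = np.array([1.0, 2.0])
        s = np.array([[1.0, 1.0], [0.0, 0.0]])
        with pytest.warns(UserWarning, match="all-zero membership"):
            T = update_centroids(x, s, 2.0, prev=np.array([0.0, 7.0]))
        assert T[1] == 7.0


class TestSpatialRegularizer:
    def test_identity_exponents_leave_membership_unchanged(self, rng):
        s = rng.dirichlet(np.ones(3), size=20).T  # 3 x 20, columns sum to 1
        out = spatial_regularize(s, (4, 5), window=3, p=1.0, q=0.0)
        np.testing.assert_allclose(out, s, atol=1e-12)

    def test_uniform_region_power_renormalization(self):
        # constant membership field: h == s, so s' ∝ s^(p+q)
        s = np.tile(np.array([[0.7], [0.3]]), (1, 25))
        out = spatial_regularize(s, (5, 5), window=3, p=1.0, q=1.0)
        expected = np.array([0.7**2, 0.3**2])
        expected /= expected.sum()
        np.testing.assert_allclose(out[:, 12], expected, atol=1e-12)

    def test_salt_noise_pixel_flips_to_surrounding_cluster(self):
        # near-crisp 5x5 region of cluster 0 with one noise pixel whose
        # membership leans to cluster 1 (FCM memberships are never exact
        # 0/1 for off-centroid pixels, and exact zeros are fixed points
        # of the multiplicative regularizer)
        s = np.tile(np.array([[0.99], [0.01]]), (1, 25))
        s[:, 12] = [0.2, 0.8]  # salt pixel
        out = spatial_regularize(s, (5, 5), window=3, p=1.0, q=1.0)
        assert out[0, 12] > out[1, 12]  # dominant membership flipped


class TestObjective:
    def test_perfect_partition_is_zero(self):
        x = np.array([0.0, 0.0, 10.0, 10.0])
        s = np.array([[1.0, 1.0, 0.0, 0.0], [0.0, 0.0, 1.0, 1.0]])
        assert weighted_objective(x, s, np.array([0.0, 10.0]), 2.0) == 0.0

    def test_single_cluster_closed_form(self, rng):
        x = rng.random(30)
        s = np.ones((1, 30))
        J = weighted_objective(x, s, np.array([x.mean()]), 2.0)
        assert J == pytest.approx(0.5 * 30 * x.var())

    def test_matches_brute_force_double_sum(self, rng):
        x = rng.random(6)
        T = np.array([0.2, 0.8])
        s = update_membership(x, T, m=2.0)
        expected = 0.5 * sum(
            s[k, l] ** 2 * (x[l] - T[k]) ** 2 for k in range(2) for l in range(6)
        )
        assert weighted_objective(x, s, T, 2.0) == pytest.approx(expected, rel=1e-12)


class TestInitContext:
    def test_constant_image_degenerate(self):
        img = as_gray(np.full((4, 4), 0.0))
        ctx = build_init_context(img, W=4, c=2)
        nz = np.nonzero(ctx.I)
        assert len(nz[0]) == 1 and nz[0][0] == nz[1][0]  # one diagonal cell
        np.testing.assert_allclose(ctx.coarse, img.pixels)

    def test_checkerboard_cooccurrence_off_diagonal(self):
        board = np.indices((6, 6)).sum(axis=0) % 2
        ctx = build_init_context(as_gray(board.astype(float)), W=2, c=2)
        assert ctx.I[0, 0] == 0 and ctx.I[1, 1] == 0
        assert ctx.I[0, 1] > 0 and ctx.I[1, 0] > 0

    def test_centroids_are_dominant_modes(self):
        # 2/3 of pixels near 0.1, 1/3 near 0.9
        vals = np.array([0.1] * 8 + [0.9] * 4).reshape(3, 4)
        ctx = build_init_context(as_gray(vals), W=4, c=2)
        assert ctx.centroids0[0] == pytest.approx(0.125, abs=0.13)
        assert ctx.centroids0[1] == pytest.approx(0.875, abs=0.13)


class TestSegment:
    def test_two_cluster_recovery_matches_reference(self):
        img = as_gray(np.array([[0.0, 0.0, 0.0], [1.0, 1.0, 1.0]]))
        cfg = SegmentationConfig(
            c=2, m=2.0, eps=1e-6, init_centroids=np.array([0.1, 0.9])
        )
        part, lmap = segment(img, cfg)
        T_ref, U_ref, _ = fcm_reference(
            img.pixels.ravel(), [0.1, 0.9], m=2.0, eps=1e-6
        )
        np.testing.assert_allclose(np.sort(part.centroids), np.sort(T_ref), atol=1e-4)
        assert lmap.labels.tolist() == [[0, 0, 0], [1, 1, 1]]

    def test_single_cluster_short_circuit(self):
        img = as_gray(np.array([[0.2, 0.4], [0.6, 0.8]]))
        part, _ = segment(img, SegmentationConfig(c=1, init_centroids=[0.3]))
        np.testing.assert_allclose(part.membership, 1.0)
        assert part.centroids[0] == pytest.approx(0.5)
        assert part.iterations == 1

    def test_objective_trace_monotone_plain_fcm(self, rng):
        img = as_gray(rng.random((8, 8)))
        part, _ = segment(img, SegmentationConfig(c=3, init="random", seed=1))
        trace = np.array(part.objective_trace)
        assert np.all(np.diff(trace) <= 1e-12)

    def test_membership_columns_conserved(self, rng):
        img = as_gray(rng.random((10, 10)))
        for spatial in (False, True):
            part, _ = segment(
                img, SegmentationConfig(c=3, spatial_enabled=spatial, init="random")
            )
            assert part.max_colsum_err <= 1e-9

    def test_invariant_to_initial_cluster_permutation(self):
        img = as_gray(np.array([[0.0, 0.1, 0.1], [0.9, 1.0, 0.9]]))
        cfg_a = SegmentationConfig(c=2, init_centroids=np.array([0.2, 0.8]))
        cfg_b = SegmentationConfig(c=2, init_centroids=np.array([0.8, 0.2]))
        _, la = segment(img, cfg_a)
        _, lb = segment(img, cfg_b)
        # same partition up to relabeling: compare centroid-rank labels
        np.testing.assert_array_equal(
            np.take(np.argsort(la.cluster_order), la.labels),
            np.take(np.argsort(lb.cluster_order), lb.labels),
        )

    def test_nonconvergence_warns_and_flags(self, rng):
        img = as_gray(rng.random((6, 6)))
        with pytest.warns(UserWarning, match="did not converge"):
            part, _ = segment(
                img, SegmentationConfig(c=3, max_iter=1, eps=1e-12, init="random")
            )
        assert not part.converged

    def test_deterministic_given_seed(self, rng):
        img = as_gray(rng.random((8, 8)))
        cfg = SegmentationConfig(c=3, init="random", seed=9)
        p1, _ = segment(img, cfg)
        p2, _ = segment(img, cfg)
        np.testing.assert_array_equal(p1.membership, p2.membership)

    def test_config_validation(self):
        with pytest.raises(ValueError, match="fuzzifier"):
            SegmentationConfig(m=0.5).validate()
        with pytest.raises(ValueError, match="eps"):
            SegmentationConfig(eps=2.0).validate()
        with pytest.raises(ValueError, match="window"):
            SegmentationConfig(window=4).validate()


class TestTumorMask:
    def test_two_region_brightest_exact(self):
        img = as_gray(np.array([[0.0, 0.0, 1.0, 1.0]] * 2))
        part, lmap = segment(
            img, SegmentationConfig(c=2, init_centroids=np.array([0.1, 0.9]))
        )
        mask = extract_tumor_mask(lmap, part)
        np.testing.assert_array_equal(mask, img.pixels > 0.5)

    def test_large_mask_warns(self):
        img = as_gray(np.array([[0.0, 1.0, 1.0, 1.0]] * 2))
        part, lmap = segment(
            img, SegmentationConfig(c=2, init_centroids=np.array([0.1, 0.9]))
        )
        with pytest.warns(UserWarning, match="half"):
            extract_tumor_mask(lmap, part)

    def test_largest_nonbackground_rule(self):
        px = np.zeros((6, 6))
        px[0, 0] = 0.6  # small bright speck
        px[3:6, 3:6] = 0.55  # large mid-intensity block
        img = as_gray(px)
        part, lmap = segment(
            img, SegmentationConfig(c=3, init_centroids=np.array([0.0, 0.55, 0.62]))
        )
        mask = extract_tumor_mask(lmap, part, rule="largest_nonbackground")
        assert mask[4, 4] and not mask[0, 0]

    def test_single_cluster_rejected(self):
        img = as_gray(np.array([[0.1, 0.9]]))
        part, lmap = segment(img, SegmentationConfig(c=1, init_centroids=[0.5]))
        with pytest.raises(ValueError, match="2 clusters"):
            extract_tumor_mask(lmap, part)


class TestKMeansBaseline:
    def test_two_value_image(self):
        img = as_gray(np.array([[0.0, 0.0, 1.0, 1.0]]))
        lmap = kmeans_baseline(img, c=2, seed=0)
        assert len(set(lmap.labels.ravel().tolist())) == 2
        assert lmap.labels[0, 0] != lmap.labels[0, 2]

    def test_matches_lloyd_oracle(self, rng):
        x = rng.random(6)
        img = as_gray(x.reshape(2, 3))
        lmap = kmeans_baseline(img, c=2, seed=0)
        _, assign = lloyd_reference(x, [x.min(), x.max()])
        ours = lmap.labels.ravel()
        groups_ours = {
            frozenset(np.where(ours == k)[0].tolist()) for k in set(ours.tolist())
        }
        groups_ref = {
            frozenset(i for i, a in enumerate(assign) if a == k) for k in set(assign)
        }
        assert groups_ours == groups_ref
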