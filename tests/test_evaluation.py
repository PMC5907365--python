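import itertools

import numpy as np
import pytest

from regmaxs import (AffineTransform, Morphology, apply_transform, centroid,
                     correspondence_distances, correspondences, pca_register,
                     pca_registration_matrix, performance_summary, sign_test)


def sign_test_enumeration(n: int, k: int) -> float:
    """Oracle: P(#successes >= k) under fair coin by explicit enumeration."""
    hits = sum(1 for flips in itertools.product((0, 1), repeat=n)
               if sum(flips) >= k)
    return hits / 2 ** n


def cloud(points, ids=None):
    n = len(points)
    ids = ids if ids is not None else range(1, n + 1)
    return Morphology(ids=ids, types=[3] * n, xyz=points, radii=[1] * n,
                      parents=[-1] * n)


class TestCorrespondences:
    def test_identical_zero_distance(self, small_tree):
        for mode in ("known", "nearest"):
            d = correspondence_distances(small_tree, small_tree, mode)
            assert np.all(d == 0)

    def test_nearest_neighbor_hand_example(self):
        ref = cloud([[0, 0, 0], [10, 0, 0]])
        test = cloud([[1, 0, 0], [20, 0, 0]])
        # ref (0,0,0) -> (1,0,0) at 1; ref (10,0,0) -> (1,0,0) at 9
        # (closer than (20,0,0) at 10); test nodes may be reused
        d = correspondence_distances(ref, test, "nearest")
        np.testing.assert_allclose(sorted(d), [1, 9])

    def test_known_mode_pairs_by_id_not_order(self):
        ref = cloud([[0, 0, 0], [10, 0, 0]], ids=[1, 2])
        test = cloud([[10, 0, 0], [0, 0, 0]], ids=[2, 1])  # reversed order
        d = correspondence_distances(ref, test, "known")
        np.testing.assert_allclose(d, [0, 0])

    def test_known_mode_requires_matching_ids(self):
        ref = cloud([[0, 0, 0]], ids=[1])
        test = cloud([[0, 0, 0]], ids=[7])
        with pytest.raises(ValueError, match="matching ids"):
            correspondences(ref, test, "known")

    def test_nearest_never_exceeds_known(self, small_tree, rng):
        noisy = small_tree.copy()
        noisy.xyz = noisy.xyz + rng.normal(0, 5, size=noisy.xyz.shape)
        d_known = correspondence_distances(small_tree, noisy, "known")
        d_nn = correspondence_distances(small_tree, noisy, "nearest")
        assert np.all(d_nn <= d_known + 1e-12)

    def test_nearest_ties_take_lowest_id(self):
        ref = cloud([[0, 0, 0]])
        test = cloud([[1, 0, 0], [-1, 0, 0]], ids=[5, 2])
        p, q = correspondences(ref, test, "nearest")
        np.testing.assert_allclose(q[0], [-1, 0, 0])  # id 2 beats id 5


class TestSignTest:
    def test_all_below(self):
        p, sig = sign_test(np.full(10, 1.0), 10.0)
        assert p == pytest.approx(0.5 ** 10)
        assert sig

    def test_half_below(self):
        d = np.r_[np.full(50, 1.0), np.full(50, 99.0)]
        p, sig = sign_test(d, 10.0)
        assert p == pytest.approx(0.5398, abs=1e-3)
        assert not sig

    def test_all_above(self):
        p, sig = sign_test(np.full(10, 99.0), 10.0)
        assert p == 1.0 and not sig

    def test_ties_count_as_failures(self):
        p_tie, _ = sign_test(np.full(10, 10.0), 10.0)
        assert p_tie == 1.0

    def test_matches_enumeration_for_all_small_n(self):
        for n in range(1, 13):
            for k in range(n + 1):
                d = np.r_[np.zeros(k), np.full(n - k, 99.0)]
                p, _ = sign_test(d, 10.0)
                assert p == pytest.approx(sign_test_enumeration(n, k),
                                          abs=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            sign_test([], 10.0)

    def test_wilcoxon_variant_runs(self):
        p, sig = sign_test(np.arange(1.0, 9.0), 10.0, method="wilcoxon")
        assert 0 <= p <= 1 and sig


class TestPerformanceSummary:
    def test_all_zero_distances(self):
        # both directions need n >= 7 for the exact test to reach p < 0.01
        assert performance_summary(np.zeros((10, 20)), 10.0) == (100.0, 100.0)

    def test_all_above_threshold(self):
        assert performance_summary(np.full((5, 20), 99.0), 10.0) == (0.0, 0.0)

    def test_mixed_tests_but_underpowered_points(self):
        # two tests all-below, one all-above, 10 points: per-test sign test
        # passes for 2/3; per-point n=3 can never reach p < 0.01
        table = np.vstack([np.zeros((2, 10)), np.full((1, 10), 99.0)])
        tests_pct, points_pct = performance_summary(table, 10.0)
        assert tests_pct == pytest.approx(100 * 2 / 3, abs=0.1)
        assert points_pct == 0.0


class TestPCARegister:
    def elongated(self, rng, n=200):
        pts = rng.normal(size=(n, 3)) * np.array([30.0, 10.0, 3.0])
        return cloud(pts)

    def test_identity_for_identical(self, rng):
        m = self.elongated(rng)
        t = pca_register(m, m)
        np.testing.assert_allclose(t.matrix(), np.eye(4), atol=1e-6)

    def test_rotation_recovered(self, rng):
        ref = self.elongated(rng)
        rot = AffineTransform(rotation_angles=[0, 0, 20], center=centroid(ref))
        test = apply_transform(ref, rot)
        t = pca_register(test, ref)
        got = np.deg2rad(t.rotation_angles)
        np.testing.assert_allclose(got, [0, 0, np.deg2rad(-20)], atol=1e-3)
        np.testing.assert_allclose(t.scales, [1, 1, 1], atol=1e-3)

    def test_scaling_difference_recovered(self, rng):
        ref = self.elongated(rng)
        test = apply_transform(
            ref, AffineTransform(scales=[1.5, 1, 1], center=centroid(ref)))
        t = pca_register(test, ref)
        assert t.scales[0] == pytest.approx(1.5, abs=1e-3)

    def test_node_order_invariance(self, rng):
        ref = self.elongated(rng)
        test = apply_transform(
            ref, AffineTransform(rotation_angles=[0, 0, 10],
                                 center=centroid(ref)))
        perm = rng.permutation(len(test))
        shuffled = cloud(test.xyz[perm])
        a = pca_register(test, ref)
        b = pca_register(shuffled, ref)
        np.testing.assert_allclose(a.rotation_angles, b.rotation_angles,
                                   atol=1e-9)

    def test_registration_matrix_aligns_exactly(self, rng):
        ref = self.elongated(rng)
        t = AffineTransform(rotation_angles=[0, 0, 25], scales=[1.4, 1.4, 1.4],
                            translation=[20, -5, 3], center=centroid(ref))
        test = apply_transform(ref, t)
        M = pca_registration_matrix(test, ref)
        back = apply_transform(test, M)
        np.testing.assert_allclose(back.xyz, ref.xyz, atol=1e-6)

    def test_degenerate_variances_warn_and_skip_rotation(self, rng):
        base = rng.normal(size=(80, 3)) * np.array([10.0, 4.0, 2.0])
        # 4-fold rotational symmetry in the xy-plane makes the covariance
        # exactly isotropic there: two equal leading variances
        pts = np.vstack([base,
                         base[:, [1, 0, 2]] * np.array([-1, 1, 1]),
                         base * np.array([-1, -1, 1]),
                         base[:, [1, 0, 2]] * np.array([1, -1, 1])])
        m = cloud(pts)
        with pytest.warns(UserWarning, match="degenerate"):
            t = pca_register(m, m)
        np.testing.assert_allclose(t.rotation_angles, [0, 0, 0], atol=1e-12)

    def test_too_few_nodes_rejected(self):
        m = cloud([[0, 0, 0], [1, 0, 0], [0, 1, 0]])
        with pytest.raises(ValueError, match="at least 4"):
            pca_register(m, m)
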