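import numpy as np
import pytest
from scipy.optimize import linprog

from regmaxs import (Morphology, OccupancyHistogram, VoxelSet, apply_transform,
                     centric_dissimilarity, dissimilarity, group_dissimilarity,
                     occupancy_histogram, voxelize)
from regmaxs.transforms import AffineTransform


def single_node(x, y, z):
    return Morphology(ids=[1], types=[1], xyz=[[x, y, z]], radii=[1],
                      parents=[-1])


def random_voxel_set(rng, v=10.0, max_extent=6, n_max=30):
    n = rng.integers(1, n_max)
    idx = rng.integers(-max_extent, max_extent, size=(n, 3))
    return VoxelSet.from_indices(v, map(tuple, idx))


def emd_to_perfect_overlap_lp(hist: OccupancyHistogram) -> float:
    """Transport-LP oracle: minimal cost moving the normalized histogram to
    the point mass at occupancy N, ground distance |i - j|."""
    N = hist.group_size
    p = hist.normalized
    bins = sorted(p)
    # flow f[k] from bin k to bin N; cost |k - N|; all mass must move there
    cost = [abs(k - N) for k in bins]
    a_eq = np.eye(len(bins))
    b_eq = [p[k] for k in bins]
    res = linprog(c=cost, A_eq=a_eq, b_eq=b_eq, bounds=[(0, None)] * len(bins))
    assert res.success
    return float(res.fun)


class TestVoxelize:
    def test_single_node_origin_voxel(self):
        assert voxelize(single_node(0, 0, 0), 10.0).indices == {(0, 0, 0)}

    def test_round_half_up_boundaries(self):
        assert voxelize(single_node(5.1, 0, 0), 10.0).indices == {(1, 0, 0)}
        assert voxelize(single_node(4.9, 0, 0), 10.0).indices == {(0, 0, 0)}
        # voxel i covers [i*v - v/2, i*v + v/2): 5.0 belongs to voxel 1
        assert voxelize(single_node(5.0, 0, 0), 10.0).indices == {(1, 0, 0)}

    def test_edge_resampling_fills_traversed_voxels(self):
        m = Morphology(ids=[1, 2], types=[1, 3],
                       xyz=[[0, 0, 0], [100, 0, 0]], radii=[1, 1],
                       parents=[-1, 1])
        vs = voxelize(m, 10.0)
        assert vs.indices == {(i, 0, 0) for i in range(11)}

    def test_invalid_voxel_size(self, toy3):
        with pytest.raises(ValueError):
            voxelize(toy3, 0.0)

    def test_translation_equivariance_by_voxel_multiples(self, small_tree):
        v = 10.0
        base = voxelize(small_tree, v)
        moved = apply_transform(
            small_tree, AffineTransform(translation=[3 * v, -2 * v, v]))
        shifted = {(i + 3, j - 2, k + 1) for i, j, k in base.indices}
        assert voxelize(moved, v).indices == shifted


class TestDissimilarity:
    def test_identical_zero(self, small_tree):
        a = voxelize(small_tree, 10.0)
        assert dissimilarity(a, a) == 0.0

    def test_disjoint_one(self):
        a = VoxelSet.from_indices(10, [(0, 0, 0), (1, 0, 0)])
        b = VoxelSet.from_indices(10, [(5, 5, 5)])
        assert dissimilarity(a, b) == 1.0

    def test_hand_formula(self):
        a = VoxelSet.from_indices(10, [(0, 0, 0), (1, 0, 0), (2, 0, 0)])
        b = VoxelSet.from_indices(10, [(0, 0, 0), (9, 9, 9)])
        assert dissimilarity(a, b) == pytest.approx(0.75)

    def test_mismatched_voxel_sizes_rejected(self):
        a = VoxelSet.from_indices(10, [(0, 0, 0)])
        b = VoxelSet.from_indices(5, [(0, 0, 0)])
        with pytest.raises(ValueError, match="voxel sizes"):
            dissimilarity(a, b)

    def test_properties_on_random_pairs(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            a, b = random_voxel_set(rng), random_voxel_set(rng)
            d_ab, d_ba = dissimilarity(a, b), dissimilarity(b, a)
            assert 0.0 <= d_ab <= 1.0
            assert d_ab == d_ba
            inter = a.indices & b.indices
            union = a.indices | b.indices
            assert d_ab == pytest.approx(1 - len(inter) / len(union))
            assert (d_ab == 0.0) == (a.indices == b.indices)
            assert (d_ab == 1.0) == (not inter)


class TestCentricDissimilarity:
    def test_pure_translation_removed(self, small_tree):
        ref = voxelize(small_tree, 10.0)
        moved = apply_transform(small_tree,
                                AffineTransform(translation=[50, 0, 0]))
        assert centric_dissimilarity(moved, ref, 10.0) == 0.0

    def test_no_offset_zero(self, small_tree):
        ref = voxelize(small_tree, 10.0)
        assert centric_dissimilarity(small_tree, ref, 10.0) == 0.0

    def test_scaled_line_matches_hand_enumeration(self, line3):
        v = 10.0
        ref = voxelize(line3, v)
        scaled = apply_transform(
            line3, AffineTransform(scales=[2, 2, 2], center=[10, 0, 0]))
        got = centric_dissimilarity(scaled, ref, v)
        # independent enumeration: densify both lines at <= v/2 spacing,
        # voxelize, align voxel-center centroids, count overlap
        def vox(lo, hi):
            pts = np.linspace(lo, hi, 64)
            return set(np.floor(pts / v + 0.5).astype(int))
        ref_ix = vox(0.0, 20.0)
        test_x = np.array(sorted(vox(-10.0, 30.0)), dtype=float)
        shift = (np.mean(list(ref_ix)) - test_x.mean()) * v
        test_ix = set(np.floor((test_x * v + shift) / v + 0.5).astype(int))
        expected = 1 - len(ref_ix & test_ix) / len(ref_ix | test_ix)
        assert got == pytest.approx(expected)


class TestOccupancyHistogram:
    def test_identical_sets_all_mass_at_n(self):
        s = VoxelSet.from_indices(10, [(0, 0, 0), (1, 0, 0), (2, 0, 0),
                                       (3, 0, 0)])
        h = occupancy_histogram([s, s])
        assert h.counts == {2: 4}
        assert h.normalized == {2: 1.0}

    def test_disjoint_sets(self):
        a = VoxelSet.from_indices(10, [(i, 0, 0) for i in range(4)])
        b = VoxelSet.from_indices(10, [(i, 5, 0) for i in range(4)])
        h = occupancy_histogram([a, b])
        assert h.counts == {1: 8}
        assert h.normalized == {1: 1.0}

    def test_partial_overlap_weighting(self):
        shared = [(i, 0, 0) for i in range(4)]
        a = VoxelSet.from_indices(10, shared + [(0, 5, 0), (1, 5, 0)])
        b = VoxelSet.from_indices(10, shared + [(0, 9, 0), (1, 9, 0)])
        h = occupancy_histogram([a, b])
        assert h.counts == {1: 4, 2: 4}
        assert h.weighted == {1: 4, 2: 8}
        assert h.normalized[1] == pytest.approx(1 / 3)
        assert h.normalized[2] == pytest.approx(2 / 3)

    def test_k_identical_sets_mass_at_k(self, small_tree):
        s = voxelize(small_tree, 20.0)
        for k in (2, 3, 5):
            h = occupancy_histogram([s] * k)
            assert set(h.counts) == {k}

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            occupancy_histogram([])


class TestGroupDissimilarity:
    def test_perfect_overlap_zero(self, small_tree):
        s = voxelize(small_tree, 10.0)
        for n in (2, 3, 5):
            assert group_dissimilarity(occupancy_histogram([s] * n)) == 0.0

    def test_partial_overlap_hand_value(self):
        h = OccupancyHistogram(2, {1: 4, 2: 4})  # normalized {1: 1/3, 2: 2/3}
        assert group_dissimilarity(h) == pytest.approx(1 / 3)

    def test_fully_disjoint_pair(self):
        h = OccupancyHistogram(2, {1: 8})
        assert group_dissimilarity(h) == pytest.approx(1.0)

    def test_normalized_variant_bounded(self):
        h = OccupancyHistogram(5, {1: 10})
        assert group_dissimilarity(h, normalized=True) == pytest.approx(1.0)

    def test_closed_form_matches_transport_lp(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            n = int(rng.integers(2, 7))
            occupied = {int(k): int(rng.integers(0, 8))
                        for k in rng.integers(1, n + 1, size=rng.integers(1, n + 1))}
            occupied = {k: c for k, c in occupied.items() if c > 0}
            if not occupied:
                occupied = {1: 1}
            h = OccupancyHistogram(n, occupied)
            assert group_dissimilarity(h) == pytest.approx(
                emd_to_perfect_overlap_lp(h), abs=1e-9)
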