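"""Binary morphology, chamfer distance, H-minima, watershed, components."""

import numpy as np
import pytest
from oracles import brute_edt, brute_erode, flood_fill_components

from pyporoscope import (
    BinaryVolume,
    DistanceVolume,
    PhantomSpec,
    StructuringElement,
    chamfer_distance,
    closing,
    dilate,
    erode,
    generate_binary_phantom,
    h_minima,
    label_components,
    opening,
    watershed,
)


class TestErodeDilate:
    def test_empty_stays_empty_full_stays_full(self):
        empty = BinaryVolume(np.zeros((6, 6, 6), bool), 1.0)
        full = BinaryVolume(np.ones((6, 6, 6), bool), 1.0)
        se = StructuringElement("cube", 3)
        assert not erode(empty, se).data.any()
        assert dilate(full, se).data.all()

    def test_single_voxel_dilates_to_cube(self):
        m = np.zeros((7, 7, 7), bool)
        m[3, 3, 3] = True
        out = dilate(BinaryVolume(m, 1.0), StructuringElement("cube", 3))
        expected = np.zeros_like(m)
        expected[2:5, 2:5, 2:5] = True
        np.testing.assert_array_equal(out.data, expected)

    @pytest.mark.parametrize("seed", range(5))
    @pytest.mark.parametrize("shape", ["cube", "ball"])
    def test_erosion_matches_brute_force(self, random_mask, seed, shape):
        mask = random_mask(shape=(10, 10, 10), seed=seed, p=0.6)
        se = StructuringElement(shape, 3)
        out = erode(mask, se)
        np.testing.assert_array_equal(out.data, brute_erode(mask.data, se.footprint()))

    @pytest.mark.parametrize("seed", range(5))
    def test_duality_with_complement(self, random_mask, seed):
        mask = random_mask(shape=(9, 9, 9), seed=seed)
        se = StructuringElement("cube", 3)
        lhs = dilate(mask, se).data
        rhs = ~erode(BinaryVolume(~mask.data, 1.0), se).data
        np.testing.assert_array_equal(lhs, rhs)

    def test_eroded_ball_sandwiched(self, ball_volume):
        ball8 = ball_volume(8).volume
        out = erode(ball8, StructuringElement("cube", 3))
        assert np.all(out.data <= ball8.data)
        inner = ball_volume(6, shape=ball8.shape).volume
        assert np.all(inner.data <= out.data)

    def test_opening_closing_idempotent_and_ordered(self, random_mask):
        mask = random_mask(shape=(12, 12, 12), seed=11, p=0.5)
        se = StructuringElement("cube", 3)
        opened = opening(mask, se)
        closed = closing(mask, se)
        assert np.all(opened.data <= mask.data)  # anti-extensive
        assert np.all(mask.data <= closed.data)  # extensive
        np.testing.assert_array_equal(opening(opened, se).data, opened.data)
        np.testing.assert_array_equal(closing(closed, se).data, closed.data)


class TestChamfer:
    def test_face_adjacent_distance_one(self):
        m = np.zeros((3, 3, 3), bool)
        m[1, 1, 1] = True
        d = chamfer_distance(BinaryVolume(m, 1.0))
        assert d.data[1, 1, 1] == pytest.approx(1.0)
        assert d.data[0, 0, 0] == 0.0

    def test_slab_midplane(self):
        slab = np.zeros((15, 9, 9), bool)
        slab[2:13] = True
        d = chamfer_distance(BinaryVolume(slab, 1.0))
        assert d.data.max() == pytest.approx(6.0)
        assert d.data[7, 4, 4] == pytest.approx(6.0)

    def test_zero_exactly_on_background(self, random_mask):
        mask = random_mask(shape=(8, 8, 8), seed=3)
        d = chamfer_distance(mask)
        assert np.all((d.data > 0) == mask.data)

    @pytest.mark.parametrize("seed", range(10))
    def test_within_chamfer_bounds_of_euclidean(self, random_mask, seed):
        mask = random_mask(shape=(8, 8, 8), seed=seed, p=0.7)
        if not mask.data.any() or mask.data.all():
            pytest.skip("degenerate draw")
        d = chamfer_distance(mask)
        exact = brute_edt(mask.data)
        obj = mask.data
        ratio = d.data[obj] / exact[obj]
        assert ratio.min() >= 0.92
        assert ratio.max() <= 1.10

    def test_all_object_rejected(self):
        with pytest.raises(ValueError):
            chamfer_distance(BinaryVolume(np.ones((4, 4, 4), bool), 1.0))


class TestHMinima:
    def _profile_volume(self):
        """1-D profile embedded in 3D: pits of depth 2 and 10 in a plateau."""
        f = np.full(30, 20.0)
        f[5:8] = 18.0  # shallow pit, depth 2
        f[18:21] = 10.0  # deep pit, depth 10
        vol = np.full((30, 3, 3), 25.0)
        vol[:, 1, 1] = f
        return DistanceVolume(vol, 1.0)

    @staticmethod
    def _regional_min_1d(f):
        from scipy import ndimage

        mins = (f == ndimage.minimum_filter(f, size=3)) & (
            f < np.max(f)
        )
        return mins

    def test_h0_identity(self):
        prof = self._profile_volume()
        np.testing.assert_array_equal(h_minima(prof, 0).data, prof.data)

    def test_shallow_pit_suppressed_deep_pit_kept(self):
        out = h_minima(self._profile_volume(), 4).data[:, 1, 1]
        # shallow pit raised to its surrounding plateau: no minimum left there
        assert out[5:8] == pytest.approx(20.0)
        # deep pit survives as a regional minimum (raised by at most h)
        assert out[18:21].min() < out[15]
        assert out[18:21].min() <= 10.0 + 4.0

    def test_constant_field_shifts_uniformly(self):
        # a constant field is one global basin: reconstruction by erosion of
        # f+h over f raises it by exactly h, leaving the relief (and any
        # downstream watershed) unchanged
        const = DistanceVolume(np.full((6, 6, 6), 7.0), 1.0)
        np.testing.assert_allclose(h_minima(const, 3).data, const.data + 3.0)

    def test_pointwise_bounds(self, random_mask):
        r = np.random.default_rng(5)
        f = DistanceVolume(r.random((10, 10, 10)) * 10, 1.0)
        for h in (0.5, 2.0, 5.0):
            out = h_minima(f, h).data
            assert np.all(out >= f.data - 1e-12)
            assert np.all(out <= f.data + h + 1e-12)

    def test_negative_h_rejected(self):
        with pytest.raises(ValueError):
            h_minima(DistanceVolume(np.zeros((3, 3, 3)), 1.0), -1)


def _two_ball_mask(centers, radii, shape):
    return generate_binary_phantom(
        PhantomSpec("balls", shape, params={"centers": centers, "radii": radii})
    ).volume


class TestWatershed:
    def test_two_disjoint_balls_two_labels(self):
        mask = _two_ball_mask([(10, 10, 10), (30, 10, 10)], [5, 5], (40, 20, 20))
        d = chamfer_distance(mask)
        lab = watershed(DistanceVolume(-d.data, 1.0), mask)
        assert lab.n_labels == 2
        # each label coincides with one ball
        for ball_c in [(10, 10, 10), (30, 10, 10)]:
            lid = lab.data[ball_c]
            single = _two_ball_mask([ball_c], [5], (40, 20, 20))
            np.testing.assert_array_equal(lab.data == lid, single.data)

    def test_single_ball_single_label(self, ball_volume):
        mask = ball_volume(6).volume
        d = chamfer_distance(mask)
        lab = watershed(DistanceVolume(-d.data, 1.0), mask)
        assert lab.n_labels == 1
        np.testing.assert_array_equal(lab.data > 0, mask.data)

    def test_overlapping_balls_split_by_h_minima(self):
        mask = _two_ball_mask([(15, 15, 15), (31, 15, 15)], [10, 10], (48, 32, 32))
        assert label_components(mask).n_labels == 1  # genuinely touching
        d = chamfer_distance(mask)
        relief = h_minima(DistanceVolume(-d.data, 1.0), 2)
        lab = watershed(relief, mask)
        assert lab.n_labels == 2
        # split near the neck plane x=23: centres end up in different labels
        assert lab.data[15, 15, 15] != lab.data[31, 15, 15]

    def test_labels_partition_mask(self, random_mask):
        mask = random_mask(shape=(12, 12, 12), seed=8, p=0.55)
        d = chamfer_distance(mask)
        lab = watershed(DistanceVolume(-d.data, 1.0), mask)
        assert np.all((lab.data > 0) == mask.data)

    def test_empty_mask_empty_labels(self):
        empty = BinaryVolume(np.zeros((5, 5, 5), bool), 1.0)
        lab = watershed(DistanceVolume(np.zeros((5, 5, 5)), 1.0), empty)
        assert lab.n_labels == 0


class TestComponents:
    def test_vertex_sharing_voxels_connectivity(self):
        m = np.zeros((4, 4, 4), bool)
        m[1, 1, 1] = True
        m[2, 2, 2] = True  # shares only a cube vertex
        assert label_components(BinaryVolume(m, 1.0), 26).n_labels == 1
        assert label_components(BinaryVolume(m, 1.0), 6).n_labels == 2

    def test_empty_volume_zero_components(self):
        assert label_components(BinaryVolume(np.zeros((4, 4, 4), bool), 1.0)).n_labels == 0

    @pytest.mark.parametrize("connectivity", [6, 18, 26])
    @pytest.mark.parametrize("seed", range(4))
    def test_matches_flood_fill_oracle(self, random_mask, connectivity, seed):
        mask = random_mask(shape=(12, 12, 12), seed=seed, p=0.35)
        lab = label_components(mask, connectivity)
        oracle = flood_fill_components(mask.data, connectivity)
        assert lab.n_labels == oracle.max()
        # same partition: labels must be a relabelling of the oracle
        for i in range(1, oracle.max() + 1):
            vals = np.unique(lab.data[oracle == i])
            assert vals.size == 1 and vals[0] > 0

    def test_bad_connectivity_rejected(self, random_mask):
        with pytest.raises(ValueError):
            label_components(random_mask(), 10)
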