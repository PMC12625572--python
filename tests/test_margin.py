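"""Anisotropic distance transform, ring extraction and the fused pipeline."""

import numpy as np
import pytest
from scipy.spatial import cKDTree

import safemargin as sm
from safemargin.errors import (
    DomainError,
    EmptyForegroundError,
    EmptyRefinedTumorError,
    ReconstructionError,
)
from tests.conftest import random_mask_pair


def volume(occ, s=(1.0, 1.0), z=None, origin=(0.0, 0.0)):
    occ = np.asarray(occ, bool)
    if z is None:
        z = np.arange(occ.shape[2], dtype=float)
    return sm.MaskVolume(occ, s[0], s[1], z, *origin)


def brute_force_distance(fg_occ, spacings):
    """All-pairs reference for the distance transform (tiny lattices only)."""
    sp = np.asarray(spacings, float)
    fg_idx = np.argwhere(fg_occ) * sp
    all_idx = np.argwhere(np.ones_like(fg_occ)) * sp
    d = np.sqrt(((all_idx[:, None, :] - fg_idx[None, :, :]) ** 2).sum(-1)).min(1)
    return d.reshape(fg_occ.shape)


class TestDistanceMap:
    def test_foreground_is_zero_and_axis_neighbor_is_one_step(self):
        occ = np.zeros((3, 3, 3), bool)
        occ[1, 1, 1] = True
        dist = sm.anisotropic_distance_map(volume(occ), (0.7, 1.0, 1.0))
        assert dist.values[1, 1, 1] == 0.0
        assert dist.values[2, 1, 1] == pytest.approx(0.7)

    def test_corner_distance_with_anisotropic_spacings(self):
        occ = np.zeros((3, 3, 3), bool)
        occ[1, 1, 1] = True
        dist = sm.anisotropic_distance_map(volume(occ), (1.0, 2.0, 3.0))
        assert dist.values[0, 0, 0] == pytest.approx(np.sqrt(14.0))

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_exact_against_all_pairs_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        shape = tuple(rng.integers(5, 12, 3))
        occ = rng.random(shape) < 0.08
        occ[tuple(s // 2 for s in shape)] = True
        sp = tuple(rng.uniform(0.3, 1.5, 3))
        dist = sm.anisotropic_distance_map(volume(occ), sp)
        np.testing.assert_allclose(
            dist.values, brute_force_distance(occ, sp), atol=1e-9
        )

    def test_empty_foreground_raises(self):
        with pytest.raises(EmptyForegroundError):
            sm.anisotropic_distance_map(volume(np.zeros((2, 2, 2))), (1, 1, 1))

    def test_lipschitz_in_each_axis(self):
        rng = np.random.default_rng(9)
        occ = rng.random((8, 8, 8)) < 0.1
        occ[4, 4, 4] = True
        sp = (0.6, 0.9, 1.3)
        d = sm.anisotropic_distance_map(volume(occ), sp).values
        for ax, step in enumerate(sp):
            diff = np.abs(np.diff(d, axis=ax))
            assert diff.max() <= step + 1e-9


class TestThresholdAndRing:
    def _dist(self):
        occ = np.zeros((5, 1, 1), bool)
        occ[0] = True
        return sm.anisotropic_distance_map(volume(occ), (1.0, 1.0, 1.0))

    def test_threshold_is_inclusive(self):
        dist = self._dist()  # distances 0,1,2,3,4 along x
        mask = sm.threshold_margin(dist, 2.0)
        assert np.flatnonzero(mask.occupancy).tolist() == [0, 1, 2]

    def test_threshold_zero_recovers_foreground(self):
        dist = self._dist()
        mask = sm.threshold_margin(dist, 0.0)
        np.testing.assert_array_equal(mask.occupancy, dist.grid.occupancy)

    def test_ring_band_is_inclusive_on_both_edges(self):
        dist = self._dist()
        # band = 2*max(spacing) = 2: keep 1 <= D <= 3
        ring = sm.extract_ring(dist, 3.0, (1.0, 1.0, 1.0))
        assert np.flatnonzero(ring.occupancy).tolist() == [1, 2, 3]

    def test_ring_requires_margin_beyond_band(self):
        with pytest.raises(DomainError):
            sm.extract_ring(self._dist(), 1.5, (1.0, 1.0, 1.0))

    def test_clip_to_bone_truth_table(self):
        rng = np.random.default_rng(2)
        a = volume(rng.random((4, 4, 3)) < 0.5)
        b = a.with_occupancy(rng.random((4, 4, 3)) < 0.5)
        out = sm.clip_to_bone(a, b)
        np.testing.assert_array_equal(out.occupancy, a.occupancy & b.occupancy)

    def test_margin_monotone_in_distance_threshold(self):
        rng = np.random.default_rng(12)
        bone, tumor = random_mask_pair(rng)
        refined = sm.refine_tumor(bone, tumor)
        dist = sm.anisotropic_distance_map(refined, (0.7, 0.9, 1.1))
        small = sm.threshold_margin(dist, 1.5).occupancy
        large = sm.threshold_margin(dist, 2.5).occupancy
        assert np.all(large[small])


class TestGenerateSafeMarginVolume:
    def test_disjoint_tumor_raises(self, small_phantom):
        bone = small_phantom.bone
        outside = bone.with_occupancy(~bone.occupancy)
        with pytest.raises(EmptyRefinedTumorError):
            sm.generate_safe_margin_volume(bone, outside, d_s=4.0, s_t=0.25)

    def test_non_positive_margin_rejected(self, small_phantom):
        with pytest.raises(DomainError):
            sm.generate_safe_margin_volume(
                small_phantom.bone, small_phantom.tumor, d_s=0.0
            )

    def test_ring_is_subset_of_fine_margin_with_banded_distances(self, small_run):
        d_s = small_run.params["d_s_mm"]
        band = small_run.params["band_width_mm"]
        ring = small_run.ring_mask.occupancy
        vals = small_run.fine_distance.values[ring]
        assert vals.max() <= d_s
        assert vals.min() >= d_s - band
        fine_margin = small_run.fine_distance.values <= d_s
        assert np.all(fine_margin[ring])

    def test_fused_points_inside_bone_and_within_margin(self, small_phantom,
                                                        small_run):
        d_s = small_run.params["d_s_mm"]
        fine_sp = small_run.params["fine_spacings_mm"]
        tumor_fine = sm.grid_to_points(small_run.fine_tumor)
        dist, _ = cKDTree(tumor_fine).query(small_run.fused_points)
        assert dist.max() <= d_s + np.sqrt(3) * max(fine_sp) + 1e-9
        # all fused points lie inside the (cuboid) bone
        hw = small_phantom.descriptor.bone_half_widths
        assert np.all(np.abs(small_run.fused_points) <= np.asarray(hw) + 1e-9)

    def test_cropping_does_not_change_the_result(self, small_phantom):
        """A pre-crop containing the full margin leaves the fused set unchanged."""
        bone, tumor = small_phantom.bone, small_phantom.tumor
        full = sm.generate_safe_margin_volume(bone, tumor, d_s=4.0, s_t=0.25,
                                              xi=1.0, keep_intermediates=False)
        box = sm.expand_bbox(sm.tumor_bbox(sm.refine_tumor(bone, tumor)),
                             4.0, 1.5)
        b_c, t_c = sm.crop_pair(bone, tumor, box)
        pre = sm.generate_safe_margin_volume(b_c, t_c, d_s=4.0, s_t=0.25,
                                             xi=1.0, keep_intermediates=False)
        a = np.array(sorted(map(tuple, full.fused_points)))
        b = np.array(sorted(map(tuple, pre.fused_points)))
        np.testing.assert_allclose(a, b, atol=1e-9)

    def test_coarse_monotone_in_margin(self, small_phantom):
        r1 = sm.generate_safe_margin_volume(
            small_phantom.bone, small_phantom.tumor, d_s=3.0, s_t=0.3,
            keep_intermediates=False)
        r2 = sm.generate_safe_margin_volume(
            small_phantom.bone, small_phantom.tumor, d_s=4.0, s_t=0.3,
            keep_intermediates=False)
        # same ROI box is not guaranteed; compare as point sets
        p1 = {tuple(p) for p in sm.grid_to_points(r1.coarse_mask)}
        p2 = {tuple(p) for p in sm.grid_to_points(r2.coarse_mask)}
        assert p1 <= p2

    def test_dedupe_removes_exact_duplicates(self, small_phantom):
        res = sm.generate_safe_margin_volume(
            small_phantom.bone, small_phantom.tumor, d_s=4.0, s_t=0.25,
            xi=1.0, dedupe=True, keep_intermediates=False)
        assert len(np.unique(res.fused_points, axis=0)) == len(res.fused_points)


class TestReconstructSurface:
    def test_tetrahedron(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], float)
        mesh = sm.reconstruct_surface(pts)
        assert len(mesh.faces) == 4

    def test_cube_corner_hull(self):
        pts = np.array(np.meshgrid([0, 1], [0, 1], [0, 1])).reshape(3, -1).T
        mesh = sm.reconstruct_surface(pts.astype(float))
        assert len(mesh.faces) == 12
        assert mesh.is_watertight

    def test_too_few_points(self):
        with pytest.raises(ReconstructionError):
            sm.reconstruct_surface(np.zeros((3, 3)))

    def test_coplanar_points(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0]], float)
        with pytest.raises(ReconstructionError):
            sm.reconstruct_surface(pts)
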