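"""Vascular morphometry against closed forms and brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import threepmorph as tpm
from threepmorph.vessel_morphometry import radius_map, smooth_path


ISO = tpm.VoxelSpacing(1.0, 1.0, 1.0)


def mask_from(arr, spacing=ISO):
    return tpm.BinaryMask(np.asarray(arr, dtype=bool), spacing)


class TestDice:
    def test_identical_masks_perfect_no_flag(self):
        m = np.zeros((4, 8, 8), bool)
        m[1:3, 2:5, 2:5] = True
        res = tpm.dice_coefficient(mask_from(m), mask_from(m.copy()))
        assert res.value == 1.0 and not res.flagged

    def test_disjoint_masks_zero_flagged(self):
        a = np.zeros((2, 8, 8), bool)
        b = np.zeros((2, 8, 8), bool)
        a[0, :2], b[1, 4:] = True, True
        res = tpm.dice_coefficient(mask_from(a), mask_from(b))
        assert res.value == 0.0 and res.flagged

    def test_half_overlap_closed_form(self):
        # |pred| = |truth| = 100, overlap 50 → 2·50/200 = 0.5, flagged
        a = np.zeros((1, 20, 20), bool)
        b = np.zeros((1, 20, 20), bool)
        a[0, :5, :20] = True  # 100 voxels
        b[0, 2:7, :20] = True  # 100 voxels, 60... rows 2-4 shared
        a_flat, b_flat = a.ravel(), b.ravel()
        overlap = int((a_flat & b_flat).sum())
        res = tpm.dice_coefficient(mask_from(a), mask_from(b))
        assert res.value == pytest.approx(2 * overlap / 200)
        assert res.flagged

    def test_both_empty_undefined(self):
        e = np.zeros((2, 4, 4), bool)
        with pytest.raises(ValueError, match="empty"):
            tpm.dice_coefficient(mask_from(e), mask_from(e.copy()))


class TestSkeletonize:
    def test_thin_line_is_its_own_skeleton(self):
        m = np.zeros((3, 9, 9), bool)
        m[1, 4, 1:8] = True
        skel = tpm.skeletonize(mask_from(m))
        assert sorted(skel.nodes) == sorted(map(tuple, np.argwhere(m)))
        assert len(skel.end_points) == 2 and not skel.branch_points

    def test_cylinder_skeleton_hugs_true_axis(self):
        m = np.zeros((40, 15, 15), bool)
        zz, yy, xx = np.mgrid[0:40, 0:15, 0:15]
        m[(yy - 7) ** 2 + (xx - 7) ** 2 <= 9] = True
        skel = tpm.skeletonize(mask_from(m))
        nodes = np.array(skel.nodes)
        inner = nodes[(nodes[:, 0] > 3) & (nodes[:, 0] < 36)]
        dev = np.hypot(inner[:, 1] - 7, inner[:, 2] - 7)
        assert dev.max() <= np.sqrt(2) + 1e-9

    def test_disjoint_tubes_two_components(self):
        m = np.zeros((3, 20, 20), bool)
        m[1, 3, 2:18] = True
        m[1, 15, 2:18] = True
        skel = tpm.skeletonize(mask_from(m))
        segs = tpm.split_segments(skel)
        assert len(segs) == 2

    def test_single_plane_component_survives_thinning(self):
        # one voxel thick in z at coarse axial sampling — must not vanish
        m = np.zeros((8, 32, 32), bool)
        m[3, 14:18, 2:30] = True
        skel = tpm.skeletonize(mask_from(m, tpm.DEFAULT_SPACING))
        assert len(skel.nodes) > 0
        assert all(m[n] for n in skel.nodes)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            tpm.skeletonize(mask_from(np.zeros((2, 4, 4), bool)))


class TestSplitSegments:
    def test_straight_line_single_segment(self):
        m = np.zeros((1, 3, 20), bool)
        m[0, 1, 1:19] = True
        skel = tpm.skeletonize(mask_from(m))
        segs = tpm.split_segments(skel)
        assert len(segs) == 1
        assert len(segs[0]) == len(skel.nodes)

    def test_y_skeleton_three_segments_sharing_branch(self):
        nodes = [(0, y, 5) for y in range(6)]
        nodes += [(0, 6, 4), (0, 7, 3), (0, 8, 2)]
        nodes += [(0, 6, 6), (0, 7, 7), (0, 8, 8)]
        m = np.zeros((1, 10, 10), bool)
        for n in nodes:
            m[n] = True
        skel = tpm.skeletonize(mask_from(m))
        assert len(skel.branch_points) == 1
        (bp,) = skel.branch_points
        segs = tpm.split_segments(skel)
        assert len(segs) == 3
        assert all(seg[0] == bp or seg[-1] == bp for seg in segs)

    def test_segment_count_matches_terminal_degree_oracle(self, demo_phantom):
        # for a branch-free forest, each segment consumes one edge slot at
        # each of its two terminals: count = Σ_terminal degree / 2
        skel = tpm.skeletonize(demo_phantom.vessel_truth_mask)
        segs = tpm.split_segments(skel, min_nodes=1)
        terminals = [n for n in skel.nodes if skel.degree(n) != 2]
        oracle = sum(skel.degree(n) for n in terminals) / 2
        assert len(segs) == oracle


class TestRadiusProfile:
    def brute_force_radius(self, mask, voxel, spacing):
        bg = np.argwhere(~mask)
        d = bg - np.asarray(voxel)
        phys = d * np.array([spacing.dz, spacing.dy, spacing.dx])
        return float(np.sqrt((phys**2).sum(axis=1)).min())

    def test_matches_brute_force_on_random_blobs(self):
        rng = np.random.default_rng(42)
        from scipy import ndimage as ndi

        for spacing in (ISO, tpm.VoxelSpacing(1.0, 1.0, 5.0)):
            field = ndi.gaussian_filter(rng.random((16, 24, 24)), 2)
            m = field > np.percentile(field, 70)
            mask = mask_from(m, spacing)
            edt = radius_map(mask)
            fg = np.argwhere(m)[::37]  # subsample foreground voxels
            for v in map(tuple, fg):
                assert edt[v] == pytest.approx(
                    self.brute_force_radius(m, v, spacing), abs=1e-9
                )

    def test_unit_line_interior_radius_one(self):
        m = np.zeros((5, 5, 9), bool)
        m[2, 2, 1:8] = True
        prof = tpm.vessel_radius_profile([(2, 2, x) for x in range(2, 7)], mask_from(m))
        np.testing.assert_allclose(prof, 1.0)

    def test_anisotropic_plane_radius_is_axial_spacing(self):
        # a filled plane with background only in z-adjacent planes: the
        # nearest background is one axial step = 5 μm away
        m = np.zeros((3, 6, 6), bool)
        m[1] = True
        mask = mask_from(m, tpm.VoxelSpacing(1.0, 1.0, 5.0))
        prof = tpm.vessel_radius_profile([(1, 3, 3), (1, 2, 4)], mask)
        np.testing.assert_allclose(prof, 5.0)

    def test_cylinder_centerline_radius(self):
        m = np.zeros((20, 15, 15), bool)
        zz, yy, xx = np.mgrid[0:20, 0:15, 0:15]
        m[(yy - 7) ** 2 + (xx - 7) ** 2 <= 9] = True
        prof = tpm.vessel_radius_profile([(z, 7, 7) for z in range(5, 15)], mask_from(m))
        assert np.all(np.abs(prof - 3.0) <= 0.5 + 1e-9)


class TestScalarMetrics:
    def test_diameter_closed_forms(self):
        assert tpm.vessel_diameter([3, 3, 3]) == 6.0
        assert tpm.vessel_diameter([1, 2, 3, 4]) == 5.0  # even-count median 2.5
        with pytest.raises(ValueError):
            tpm.vessel_diameter([])

    def test_length_closed_forms(self):
        assert tpm.vessel_length([(0, 0, 0), (3, 4, 0)]) == pytest.approx(5.0)
        pts = [(0.98 * i, 0, 0) for i in range(11)]
        assert tpm.vessel_length(pts) == pytest.approx(9.8)

    def test_length_matches_resummation_oracle(self):
        rng = np.random.default_rng(7)
        pts = rng.random((50, 3)) * 100
        oracle = sum(
            float(np.linalg.norm(pts[i + 1] - pts[i])) for i in range(49)
        )
        assert tpm.vessel_length(pts) == pytest.approx(oracle, rel=1e-9)

    def test_tortuosity_straight_and_folded(self):
        assert tpm.vessel_tortuosity([(0, 0, 0), (5, 0, 0), (9, 0, 0)]) == pytest.approx(
            1.0, abs=1e-9
        )
        # path 5 + 5 = 10 against chord 8
        assert tpm.vessel_tortuosity([(0, 0, 0), (4, 3, 0), (8, 0, 0)]) == pytest.approx(
            1.25
        )

    def test_tortuosity_semicircle_approaches_half_pi(self):
        theta = np.linspace(0, np.pi, 64)  # ~1-voxel arc steps at r = 20
        pts = np.column_stack([20 * np.cos(theta), 20 * np.sin(theta), 0 * theta])
        assert tpm.vessel_tortuosity(pts) == pytest.approx(np.pi / 2, rel=0.02)

    def test_closed_loop_tortuosity_undefined(self):
        with pytest.raises(ValueError, match="undefined"):
            tpm.vessel_tortuosity([(0, 0, 0), (1, 0, 0), (1, 1, 0), (0, 0, 0)])

    def test_total_volume_identity(self):
        m = np.zeros((10, 10, 10), bool)
        m.flat[np.random.default_rng(1).choice(1000, 321, replace=False)] = True
        mask = tpm.BinaryMask(m, tpm.DEFAULT_SPACING)
        vol = tpm.total_vessel_volume(mask)
        assert vol == pytest.approx(321 * 0.98 * 0.98 * 5.0)
        # Eq-style identity: volume / voxel volume is exactly the voxel count
        assert vol / mask.spacing.voxel_volume == pytest.approx(321, abs=1e-9)

    def test_empty_mask_zero_volume(self):
        assert tpm.total_vessel_volume(mask_from(np.zeros((2, 3, 3), bool))) == 0.0


class TestInterVesselDistance:
    def test_two_segments_symmetric(self):
        ivd = tpm.inter_vessel_distance([(0, 0, 0), (10, 0, 0)])
        np.testing.assert_allclose(ivd, [10.0, 10.0])

    def test_three_collinear_nearest_neighbour(self):
        ivd = tpm.inter_vessel_distance([(0, 0, 0), (5, 0, 0), (12, 0, 0)])
        np.testing.assert_allclose(ivd, [5.0, 5.0, 7.0])

    def test_matches_brute_force_all_pairs(self):
        rng = np.random.default_rng(20)
        cents = rng.random((20, 3)) * 200
        ivd = tpm.inter_vessel_distance(cents)
        for i in range(20):
            oracle = min(
                float(np.linalg.norm(cents[i] - cents[j])) for j in range(20) if j != i
            )
            assert ivd[i] == pytest.approx(oracle, abs=1e-9)

    def test_permutation_invariant(self):
        rng = np.random.default_rng(21)
        cents = rng.random((12, 3)) * 50
        perm = rng.permutation(12)
        a = tpm.inter_vessel_distance(cents)
        b = tpm.inter_vessel_distance(cents[perm])
        np.testing.assert_allclose(a[perm], b)

    def test_single_segment_rejected(self):
        with pytest.raises(ValueError):
            tpm.inter_vessel_distance([(0, 0, 0)])


class TestBaselineSegment:
    def test_inversion_flag_symmetry(self):
        rng = np.random.default_rng(3)
        v = rng.random((8, 32, 32)) * 20
        v[3:5, 10:20, 10:20] += 200
        stack = tpm.ImageStack(v, ISO, bit_depth_max=255.0)
        inv = tpm.ImageStack(v.max() - v, ISO, bit_depth_max=255.0)
        a = tpm.baseline_segment(stack)
        b = tpm.baseline_segment(inv, invert=True)
        np.testing.assert_array_equal(a.voxels, b.voxels)

    def test_constant_stack_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            tpm.baseline_segment(tpm.ImageStack(np.full((2, 8, 8), 7.0), ISO))

    def test_pure_background_noise_gives_empty_mask(self):
        rng = np.random.default_rng(9)
        v = rng.normal(10, 1, (8, 64, 64)).clip(0)
        mask = tpm.baseline_segment(tpm.ImageStack(v, ISO, bit_depth_max=255.0))
        assert mask.count == 0


class TestScalingProperties:
    @given(st.floats(min_value=0.5, max_value=4.0))
    @settings(max_examples=20, deadline=None)
    def test_length_and_tortuosity_under_uniform_scaling(self, c):
        pts = np.array([[0, 0, 0], [3, 1, 0], [6, 0, 2], [9, 2, 4]], float)
        assert tpm.vessel_length(pts * c) == pytest.approx(c * tpm.vessel_length(pts))
        assert tpm.vessel_tortuosity(pts * c) == pytest.approx(
            tpm.vessel_tortuosity(pts), rel=1e-9
        )

    def test_volume_scales_cubically_with_spacing(self):
        m = np.zeros((4, 4, 4), bool)
        m[1:3, 1:3, 1:3] = True
        v1 = tpm.total_vessel_volume(tpm.BinaryMask(m, tpm.VoxelSpacing(1, 1, 1)))
        v2 = tpm.total_vessel_volume(tpm.BinaryMask(m, tpm.VoxelSpacing(2, 2, 2)))
        assert v2 == pytest.approx(8 * v1)


class TestSmoothPath:
    def test_straight_path_unchanged_direction(self):
        pts = np.column_stack([np.arange(30.0), np.zeros(30), np.zeros(30)])
        sm = smooth_path(pts, window=7)
        np.testing.assert_allclose(sm[:, 1:], 0.0, atol=1e-12)

    def test_staircase_tortuosity_deflated_toward_unity(self):
        # digital staircase of an oblique line: raw path length inflated,
        # smoothed path goes back near the chord
        t = np.arange(60.0)
        pts = np.column_stack([t, np.round(t * 0.4), np.zeros_like(t)])
        raw = tpm.vessel_tortuosity(pts)
        smoothed = tpm.vessel_tortuosity(smooth_path(pts, window=15))
        assert smoothed < raw
        assert smoothed == pytest.approx(1.0, abs=0.01)
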