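"""Preprocessing chain contracts and motion assessment."""

import numpy as np
import pytest

import threepmorph as tpm
from .conftest import axial_tube_spec

ISO = tpm.VoxelSpacing(1.0, 1.0, 1.0)


def stack_of(arr, bdm=255.0, spacing=ISO):
    return tpm.ImageStack(np.asarray(arr, float), spacing, bit_depth_max=bdm)


def hist_entropy(plane, bins=64, full_scale=255.0):
    # entropy over the full intensity scale: a low-contrast plane occupies
    # few bins, an equalized one spreads across the range
    h, _ = np.histogram(plane, bins=bins, range=(0.0, full_scale))
    p = h[h > 0] / h.sum()
    return float(-(p * np.log2(p)).sum())


class TestAdaptiveHistEq:
    def test_constant_stack_passes_through(self):
        s = stack_of(np.full((3, 32, 32), 40.0))
        out = tpm.adaptive_hist_eq(s)
        np.testing.assert_allclose(out.voxels, 40.0)

    def test_range_contract(self):
        rng = np.random.default_rng(0)
        s = stack_of(rng.random((4, 64, 64)) * 255)
        out = tpm.adaptive_hist_eq(s)
        assert out.voxels.min() >= 0.0
        assert out.voxels.max() <= 255.0 + 1e-9

    def test_low_contrast_plane_entropy_increases(self):
        rng = np.random.default_rng(1)
        base = rng.random((64, 64)) * 10 + 100  # narrow range
        s = stack_of(base[None])
        out = tpm.adaptive_hist_eq(s)
        assert hist_entropy(out.voxels[0]) >= hist_entropy(s.voxels[0])

    def test_shape_preserved(self):
        rng = np.random.default_rng(2)
        s = stack_of(rng.random((5, 48, 40)) * 200)
        assert tpm.adaptive_hist_eq(s).shape == s.shape


class TestRemoveCrosstalk:
    def test_alpha_zero_identity(self):
        rng = np.random.default_rng(3)
        t = stack_of(rng.random((3, 16, 16)) * 100)
        s = stack_of(rng.random((3, 16, 16)) * 100)
        out = tpm.remove_crosstalk(t, s, alpha=0.0)
        np.testing.assert_array_equal(out.voxels, t.voxels)

    def test_full_subtraction_clamps_to_zero(self):
        t = stack_of(np.full((2, 8, 8), 5.0))
        s = stack_of(np.full((2, 8, 8), 100.0))
        out = tpm.remove_crosstalk(t, s, alpha=0.5)
        np.testing.assert_array_equal(out.voxels, 0.0)

    def test_auto_recovers_known_alpha_noiselessly(self):
        spec = tpm.demo_phantom_spec(seed=4, crosstalk_alpha=0.2)
        res = tpm.generate_phantom(spec)
        est = tpm.estimate_crosstalk_alpha(res.vessel, res.plaque)
        assert est == pytest.approx(0.2, abs=0.05)
        est2 = tpm.estimate_crosstalk_alpha(res.plaque, res.vessel)
        assert est2 == pytest.approx(0.2, abs=0.05)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            tpm.remove_crosstalk(
                stack_of(np.zeros((2, 8, 8))), stack_of(np.zeros((3, 8, 8)))
            )


class TestRemoveDura:
    def test_boundary_zero_noop(self):
        rng = np.random.default_rng(4)
        s = stack_of(rng.random((6, 8, 8)))
        out = tpm.remove_dura(s, boundary=0)
        np.testing.assert_array_equal(out.voxels, s.voxels)

    def test_boundary_slices_planes(self):
        rng = np.random.default_rng(5)
        s = stack_of(rng.random((64, 8, 8)))
        out = tpm.remove_dura(s, boundary=3)
        assert out.nz == 61
        np.testing.assert_array_equal(out.voxels[0], s.voxels[3])

    def test_from_thg_locates_bright_band(self):
        v = np.full((64, 16, 16), 5.0)
        thg = np.full((64, 16, 16), 2.0)
        thg[:3] = 120.0  # dura band in planes 0-2
        out = tpm.remove_dura(stack_of(v), boundary="from-thg", thg=stack_of(thg))
        assert out.nz == 61

    def test_boundary_beyond_depth_rejected(self):
        s = stack_of(np.zeros((4, 4, 4)))
        with pytest.raises(ValueError):
            tpm.remove_dura(s, boundary=4)
        with pytest.raises(ValueError, match="THG"):
            tpm.remove_dura(s, boundary="from-thg")


class TestNormalizeStack:
    def test_already_uniform_ranges_unchanged(self):
        rng = np.random.default_rng(6)
        plane = rng.random((16, 16)) * 100
        s = stack_of(np.stack([plane, plane, plane]))
        out = tpm.normalize_stack(s)
        np.testing.assert_allclose(out.voxels, s.voxels, atol=1e-9)

    def test_two_plane_linear_map(self):
        p0 = np.linspace(0, 255, 256).reshape(16, 16)
        p1 = np.linspace(10, 0.5 * 255, 256).reshape(16, 16)
        s = stack_of(np.stack([p0, p1]))
        out = tpm.normalize_stack(s, saturation_fraction=0.95)
        # plane 1 (max 127.5 ≤ 0.95·255) is the reference; plane 0 mapped onto it
        assert out.voxels[0].min() == pytest.approx(10.0)
        assert out.voxels[0].max() == pytest.approx(127.5)
        np.testing.assert_allclose(out.voxels[1], p1)

    def test_attenuating_phantom_ranges_equalized(self):
        # tubes span the full depth so every plane (incl. the reference,
        # the deepest one) contains structure
        tubes = [
            tpm.straight_tube((60.0, 60.0, 0.0), (60.0, 60.0, 315.0), 3.0),
            tpm.straight_tube((180.0, 170.0, 0.0), (180.0, 170.0, 315.0), 4.0),
        ]
        spec = tpm.PhantomSpec(
            shape=(64, 256, 256), vessels=tubes, attenuation_length=150.0, seed=3
        )
        res = tpm.generate_phantom(spec)
        raw_maxes = res.vessel.voxels.max(axis=(1, 2))
        assert raw_maxes[-1] < 0.5 * raw_maxes[0]  # strong attenuation before
        out = tpm.normalize_stack(res.vessel)
        maxes = out.voxels.max(axis=(1, 2))
        assert maxes.max() - maxes.min() <= 0.05 * maxes.max()

    def test_constant_reference_passes_through(self, caplog):
        s = stack_of(np.full((3, 8, 8), 9.0))
        out = tpm.normalize_stack(s)
        np.testing.assert_array_equal(out.voxels, s.voxels)


class TestDenoise:
    def test_constant_unchanged(self):
        s = stack_of(np.full((4, 8, 8), 3.0))
        np.testing.assert_array_equal(tpm.denoise(s).voxels, 3.0)

    def test_impulse_removed(self):
        v = np.full((5, 9, 9), 10.0)
        v[2, 4, 4] = 200.0
        out = tpm.denoise(stack_of(v), radius=1)
        np.testing.assert_allclose(out.voxels, 10.0)

    def test_rmse_to_truth_decreases(self):
        spec = axial_tube_spec(seed=8, gaussian_sd=8.0)
        clean = tpm.generate_phantom(axial_tube_spec(seed=8)).vessel.voxels
        noisy = tpm.generate_phantom(spec).vessel
        den = tpm.denoise(noisy)
        rmse_before = np.sqrt(((noisy.voxels - clean) ** 2).mean())
        rmse_after = np.sqrt(((den.voxels - clean) ** 2).mean())
        assert rmse_after < rmse_before


class TestAssessMotion:
    def test_static_axial_tubes_zero_shift(self, axial_phantom):
        report = tpm.assess_motion(axial_phantom.vessel)
        assert report.max_shift == pytest.approx(0.0, abs=1e-9)

    def test_single_plane_jitter_recovered(self):
        jitter = [(0, 0)] * 64
        jitter[30] = (0, 3)
        res = tpm.generate_phantom(axial_tube_spec(seed=1, jitter=jitter))
        report = tpm.assess_motion(res.vessel)
        assert report.max_shift == pytest.approx(3.0, abs=0.5)
        # the jittered plane pair is the one reporting the max
        planes = [p for p, _, s in report.shifts if s > 1.0]
        assert 30 in planes or 31 in planes

    def test_max_shift_is_maximum_of_list(self, axial_phantom):
        report = tpm.assess_motion(axial_phantom.vessel)
        assert report.max_shift == max(s for _, _, s in report.shifts)

    def test_no_foreground_rejected(self):
        s = stack_of(np.full((4, 16, 16), 2.0))
        with pytest.raises(ValueError):
            tpm.assess_motion(s)


class TestPipeline:
    def test_shapes_preserved_except_dura(self):
        spec = axial_tube_spec(seed=10, attenuation_length=200.0)
        res = tpm.generate_phantom(spec)
        cfg = dict(tpm.DEFAULT_CONFIG)
        cfg["dura_boundary"] = 2
        out = tpm.preprocess_stack(res.vessel, cfg=cfg)
        assert out.shape == (62, 256, 256)
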