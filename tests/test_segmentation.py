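"""Contouring, filtering, thresholding and BV/TV calibration."""

import numpy as np
import pytest

from cortigap.errors import CalibrationError, ContourValidationError, EmptyContourError
from cortigap.segmentation import (
    ContourParams,
    LowresParams,
    PeriostealMask,
    accept_manual_contour,
    auto_contour,
    calibrate_threshold_to_bvtv,
    segment_highres,
    segment_lowres,
)
from cortigap.volume_io import GrayVolume


def hollow_cylinder(n=32, r_out=12.0, r_in=8.0, value=1000.0):
    ax = np.arange(n) - (n - 1) / 2
    yy, xx = np.meshgrid(ax, ax, indexing="ij")
    annulus = (np.hypot(yy, xx) <= r_out) & (np.hypot(yy, xx) >= r_in)
    data = np.zeros((12, n, n))
    data[:, annulus] = value
    return GrayVolume(data, 0.082)


class TestAutoContour:
    def test_hollow_cylinder_mask_is_filled(self):
        vol = hollow_cylinder()
        mask = auto_contour(vol)
        # every slice is a filled disc: annulus interior included
        ax = np.arange(32) - 31 / 2
        yy, xx = np.meshgrid(ax, ax, indexing="ij")
        lumen = np.hypot(yy, xx) < 7.0
        assert mask.inside[:, lumen].all()
        assert mask.inside[vol.data >= 500].all()

    def test_all_zero_volume_raises(self):
        with pytest.raises(EmptyContourError):
            auto_contour(GrayVolume(np.zeros((8, 8, 8)), 0.082))

    def test_idempotent_on_binary_mask(self):
        vol = hollow_cylinder()
        mask = auto_contour(vol)
        again = auto_contour(GrayVolume(mask.inside.astype(float), vol.voxel_size_mm))
        np.testing.assert_array_equal(again.inside, mask.inside)

    def test_two_bones_split_components(self):
        data = np.zeros((8, 20, 44))
        data[2:6, 6:14, 4:18] = 1000.0
        data[2:6, 6:14, 26:40] = 1000.0
        vol = GrayVolume(data, 0.082)
        masks = auto_contour(vol, ContourParams(split_components=True, closing_radius=1))
        assert len(masks) == 2
        single = auto_contour(vol, ContourParams(split_components=False, closing_radius=1))
        assert single.inside.sum() < sum(m.inside.sum() for m in masks)


class TestManualContour:
    def test_supplied_mask_with_hole_filled_and_warns(self):
        arr = np.zeros((4, 12, 12), bool)
        arr[:, 2:10, 2:10] = True
        arr[:, 5:7, 5:7] = False  # internal hole
        with pytest.warns(UserWarning, match="hole"):
            mask = accept_manual_contour(arr, voxel_size_mm=0.082)
        assert mask.inside[:, 5:7, 5:7].all()

    def test_mask_smaller_than_bone_rejected(self):
        arr = np.zeros((4, 10, 10), bool)
        arr[:, 3:7, 3:7] = True
        bone = np.zeros_like(arr)
        bone[:, 1:9, 1:9] = True
        with pytest.raises(ContourValidationError):
            accept_manual_contour(arr, voxel_size_mm=0.082, bone=bone)


class TestSegmentHighres:
    def _mask(self, shape):
        return PeriostealMask(np.ones(shape, bool), 0.018)

    @pytest.mark.parametrize("permille,expect_bone", [(300, True), (200, False)])
    def test_constant_volume_against_247_threshold(self, permille, expect_bone):
        vol = GrayVolume(np.full((8, 8, 8), permille / 1000 * 1000.0), 0.018)
        seg = segment_highres(vol, self._mask(vol.shape), max_value=1000.0)
        assert seg.bone.all() == expect_bone
        assert seg.bvtv == pytest.approx(1.0 if expect_bone else 0.0)

    def test_matches_direct_convolution_oracle(self):
        rng = np.random.default_rng(5)
        data = rng.uniform(0, 1000, (16, 16, 16))
        vol = GrayVolume(data, 0.018)
        seg = segment_highres(vol, self._mask(vol.shape), max_value=1000.0)
        # dense separable convolution with the truncated (radius 1) kernel
        sigma = 0.8
        w = np.exp(-np.arange(-1, 2) ** 2 / (2 * sigma**2))
        w /= w.sum()
        filt = data.copy()
        for ax in range(3):
            # 'symmetric' matches ndimage's 'reflect' (edge value repeated)
            padded = np.pad(filt, [(1, 1) if a == ax else (0, 0) for a in range(3)], mode="symmetric")
            sl = [slice(None)] * 3
            acc = np.zeros_like(filt)
            for i, wi in enumerate(w):
                sl[ax] = slice(i, i + filt.shape[ax])
                acc += wi * padded[tuple(sl)]
            filt = acc
        expected = filt >= 247.0
        # voxel-exact away from ties (none expected with continuous data)
        np.testing.assert_array_equal(seg.bone, expected)


class TestSegmentLowres:
    def test_noise_free_shell_plain_threshold_recovers_exactly(self):
        vol = hollow_cylinder()
        mask = auto_contour(vol)
        seg = segment_lowres(vol, mask, LowresParams(filter="none", threshold_permille=500))
        np.testing.assert_array_equal(seg.bone, vol.data >= 500)

    def test_minimum_threshold_gives_bvtv_one(self):
        vol = hollow_cylinder()
        mask = auto_contour(vol)
        seg = segment_lowres(vol, mask, LowresParams(filter="none", threshold_permille=0))
        assert seg.bvtv == pytest.approx(1.0)

    def test_bvtv_monotone_in_threshold(self):
        rng = np.random.default_rng(2)
        vol = GrayVolume(rng.uniform(0, 1000, (10, 12, 12)), 0.082)
        mask = PeriostealMask(np.ones(vol.shape, bool), 0.082)
        bvtvs = [
            segment_lowres(vol, mask, LowresParams(filter="none", threshold_permille=p)).bvtv
            for p in (100, 300, 500, 700, 900)
        ]
        assert all(a >= b for a, b in zip(bvtvs, bvtvs[1:]))


class TestCalibration:
    def test_order_statistic_matches_quantile(self):
        rng = np.random.default_rng(3)
        vol = GrayVolume(rng.uniform(0, 1000, (20, 20, 20)), 0.018)
        mask = PeriostealMask(np.ones(vol.shape, bool), 0.018)
        thr = calibrate_threshold_to_bvtv(vol, mask, 0.25)
        achieved = (vol.data >= thr).mean()
        assert abs(achieved - 0.25) <= 1.0 / vol.data.size + 1e-12

    def test_forty_percent_target_returns_boundary_value(self):
        vals = np.arange(1000, dtype=float)
        rng = np.random.default_rng(4)
        rng.shuffle(vals)
        vol = GrayVolume(vals.reshape(10, 10, 10), 0.018)
        mask = PeriostealMask(np.ones(vol.shape, bool), 0.018)
        thr = calibrate_threshold_to_bvtv(vol, mask, 0.40)
        assert (vol.data >= thr).mean() == pytest.approx(0.40)

    def test_unreachable_target_on_binary_image(self):
        data = np.zeros((10, 10, 10))
        data[:5] = 1000.0
        vol = GrayVolume(data, 0.018)
        mask = PeriostealMask(np.ones(vol.shape, bool), 0.018)
        with pytest.raises(CalibrationError):
            calibrate_threshold_to_bvtv(vol, mask, 0.999)
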