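"""Rigid transforms, registration recovery, label resampling, overlap matching."""

import numpy as np
import pandas as pd
import pytest

from cortigap.errors import GeometryMismatchError
from cortigap.interruption_detect import DiameterSpec, InterruptionSet
from cortigap.registration_matching import (
    MatchReport,
    RigidTransform,
    match_interruptions,
    overlap_volume_mm3,
    register_rigid,
    resample_labels,
)
from cortigap.volume_io import GrayVolume, LabelVolume


def make_set(data: np.ndarray, voxel=0.082) -> InterruptionSet:
    labels = LabelVolume(data.astype(np.int32), voxel)
    present = np.unique(data)
    present = present[present > 0]
    counts = [int((data == l).sum()) for l in present]
    table = pd.DataFrame(
        {
            "label": present,
            "voxel_count": counts,
            "volume_mm3": np.asarray(counts) * voxel**3,
            "surface_mm2": np.nan,
        }
    )
    return InterruptionSet(labels, table, DiameterSpec(1, voxel))


class TestRigidTransform:
    def test_inverse_and_compose_are_consistent(self):
        t = RigidTransform.from_euler_deg((10.0, -5.0, 3.0), (1.0, -2.0, 0.5))
        pts = np.random.default_rng(0).normal(size=(20, 3))
        np.testing.assert_allclose(t.inverse().apply(t.apply(pts)), pts, atol=1e-12)
        ident = t.compose(t.inverse())
        # arccos amplifies rounding near the identity; 1e-5 deg is numerically tight
        assert ident.rotation_angle_deg == pytest.approx(0.0, abs=1e-5)
        assert abs(np.linalg.det(t.rotation) - 1.0) < 1e-9

    def test_improper_rotation_rejected(self):
        bad = np.diag([1.0, 1.0, -1.0])
        with pytest.raises(ValueError):
            RigidTransform(bad, np.zeros(3))


class TestRegistration:
    @staticmethod
    def _volume():
        # asymmetric blocky object so all six rigid parameters are pinned
        data = np.zeros((48, 48, 48))
        data[10:38, 12:30, 14:34] = 1000.0
        data[14:22, 14:20, 30:40] = 1000.0
        data[28:36, 24:36, 10:16] = 1000.0
        rng = np.random.default_rng(2)
        return GrayVolume(data + rng.normal(0, 40, data.shape), 0.082)

    def test_fixed_equals_moving_recovers_identity(self):
        vol = self._volume()
        tf = register_rigid(vol, vol)
        assert tf.rotation_angle_deg < 0.1
        assert np.abs(tf.translation_mm).max() < 0.02

    def test_known_perturbation_recovered(self):
        import SimpleITK as sitk

        from cortigap.registration_matching import _rigid_to_sitk, _to_sitk

        fixed = self._volume()
        true = RigidTransform.from_euler_deg((5.0, -2.0, 1.5), (0.3, -0.25, 0.15))
        # synthesize the moving volume by resampling fixed through true^-1
        img = _to_sitk(fixed)
        moved = sitk.Resample(img, img, _rigid_to_sitk(true.inverse()), sitk.sitkLinear, 0.0)
        moving = GrayVolume(sitk.GetArrayFromImage(moved).astype(float), 0.082)
        tf = register_rigid(moving, fixed)
        resid = tf.compose(true.inverse())
        assert resid.rotation_angle_deg < 0.5
        center = fixed.origin_mm + np.asarray(fixed.shape) * 0.082 / 2
        assert np.linalg.norm(resid.apply(center[None])[0] - center) < 0.1


class TestResampleLabels:
    def test_identity_same_grid_is_noop(self):
        rng = np.random.default_rng(1)
        data = rng.integers(0, 4, (12, 12, 12)).astype(np.int32)
        lab = LabelVolume(data, 0.082)
        out = resample_labels(lab, RigidTransform.identity(), lab)
        np.testing.assert_array_equal(out.data, data)

    def test_label_outside_target_field_maps_to_zero(self):
        data = np.zeros((8, 8, 8), np.int32)
        data[2:5, 2:5, 2:5] = 1
        lab = LabelVolume(data, 0.082)
        shift = RigidTransform(np.eye(3), np.array([100.0, 0.0, 0.0]))
        out = resample_labels(lab, shift, lab)
        assert not out.data.any()

    def test_fine_sphere_downscale_preserves_volume(self):
        vs_h, vs_l, r = 0.018, 0.082, 0.30
        n = int(np.ceil(2 * (r + 0.1) / vs_h))
        ax = (np.arange(n) - (n - 1) / 2) * vs_h
        zz, yy, xx = np.meshgrid(ax, ax, ax, indexing="ij")
        sph = (zz**2 + yy**2 + xx**2 <= r**2).astype(np.int32)
        lab = LabelVolume(sph, vs_h, np.array([ax[0]] * 3))
        nl = int(np.ceil(2 * (r + 0.15) / vs_l))
        axl = (np.arange(nl) - (nl - 1) / 2) * vs_l
        out = resample_labels(lab, RigidTransform.identity(), ((nl, nl, nl), vs_l, np.array([axl[0]] * 3)))
        expected = sph.sum() * (vs_h / vs_l) ** 3
        assert abs(int((out.data == 1).sum()) - expected) <= 2

    def test_round_trip_keeps_most_of_large_components(self):
        data = np.zeros((30, 30, 30), np.int32)
        data[8:20, 8:20, 8:20] = 1  # 1728 voxels >= 100
        lab = LabelVolume(data, 0.082)
        t = RigidTransform.from_euler_deg((7.0, 3.0, -4.0), (0.12, -0.2, 0.07))
        fwd = resample_labels(lab, t, lab)
        back = resample_labels(fwd, t.inverse(), lab)
        kept = ((back.data == 1) & (data == 1)).sum() / (data == 1).sum()
        assert kept >= 0.9


class TestMatching:
    def test_identical_maps_match_bijectively(self):
        rng = np.random.default_rng(3)
        data = np.zeros((20, 20, 20), np.int32)
        data[2:6, 2:8, 2:8] = 1   # 144 voxels
        data[10:14, 10:16, 10:16] = 2
        s = make_set(data)
        rep = match_interruptions(s, LabelVolume(data, 0.082))
        assert rep.matched_A == rep.matched_B == rep.n_A == rep.n_B == 2
        assert sorted((a, b) for a, b, _ in rep.pairs) == [(1, 1), (2, 2)]

    def test_nineteen_voxel_overlap_is_not_a_match(self):
        a = np.zeros((10, 10, 10), np.int32)
        a[0:5, 0:5, 0:5] = 1
        b = np.zeros_like(a)
        b[0:1, 0:5, 0:4] = 1  # overlap 20 -> shrink to 19
        b[0, 4, 3] = 0
        overlap = int(((a > 0) & (b > 0)).sum())
        assert overlap == 19
        rep = match_interruptions(make_set(a), LabelVolume(b, 0.082))
        assert rep.pairs == [] and rep.matched_A == 0

    def test_one_A_component_matching_two_B_components(self):
        a = np.zeros((10, 12, 12), np.int32)
        a[:, 2:10, 2:10] = 1
        b = np.zeros_like(a)
        b[0:3, 3:8, 3:8] = 1   # 75 voxels overlap
        b[6:9, 3:8, 3:8] = 2   # 75 voxels overlap
        rep = match_interruptions(make_set(a), LabelVolume(b, 0.082))
        assert rep.matched_A == 1
        assert rep.matched_B == 2
        assert len(rep.pairs) == 2

    def test_pair_existence_is_symmetric(self):
        rng = np.random.default_rng(4)
        a = (rng.random((16, 16, 16)) < 0.3).astype(np.int32)
        from scipy import ndimage

        a, _ = ndimage.label(a)
        b = np.roll(a, 2, axis=1)
        rep_ab = match_interruptions(make_set(a), LabelVolume(b.astype(np.int32), 0.082), overlap_min=5)
        rep_ba = match_interruptions(make_set(b), LabelVolume(a.astype(np.int32), 0.082), overlap_min=5)
        assert {(x, y) for x, y, _ in rep_ab.pairs} == {(y, x) for x, y, _ in rep_ba.pairs}

    def test_geometry_mismatch_rejected(self):
        a = np.zeros((5, 5, 5), np.int32)
        with pytest.raises(GeometryMismatchError):
            match_interruptions(make_set(a), LabelVolume(np.zeros((6, 5, 5), np.int32), 0.082))

    def test_report_invariants_enforced(self):
        with pytest.raises(ValueError):
            MatchReport("fixed_ref_diameter", [(1, 1, 5)], 1, 1, 1, 1, overlap_min=20)


@pytest.mark.parametrize(
    "n,voxel,expected",
    [(20, 0.082, 0.011), (1, 1.0, 1.0), (20, 0.018, 0.000)],
)
def test_overlap_volume_reporting(n, voxel, expected):
    assert overlap_volume_mm3(n, voxel) == pytest.approx(expected, abs=5e-4)
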