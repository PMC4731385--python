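"""Registration stand-in, mask propagation, and the two false-positive filters."""

import numpy as np
import pytest

from flairmap.fp_filters import (
    AffineTransform,
    Plane,
    filter_by_wm_overlap,
    make_flair_like_reference,
    make_wm_mask,
    midline_distances,
    midline_filter,
    register_affine,
    resample_to_subject,
    synthetic_atlas,
)
from flairmap.lesion_extraction import label_components
from flairmap.volume_io import BinaryMask, Volume


def _ellipsoid_mask(shape=(48, 48, 48), center=(24, 24, 24), semi=(14, 18, 12), affine=None):
    idx = np.indices(shape, dtype=float)
    q = sum(((idx[i] - center[i]) / semi[i]) ** 2 for i in range(3))
    return BinaryMask(q <= 1.0, affine if affine is not None else np.eye(4))


class TestRegisterAffine:
    def test_self_registration_is_identity(self):
        m = _ellipsoid_mask()
        t = register_affine(m, m)
        np.testing.assert_allclose(t.matrix, np.eye(4), atol=1e-6)

    def test_translation_recovery(self):
        atlas = _ellipsoid_mask()
        shift = np.eye(4)
        shift[:3, 3] = [5.0, -3.0, 2.0]
        subject = BinaryMask(atlas.data.copy(), shift @ atlas.affine)
        t = register_affine(subject, atlas)
        np.testing.assert_allclose(t.matrix[:3, 3], [5.0, -3.0, 2.0], atol=0.5)
        np.testing.assert_allclose(t.matrix[:3, :3], np.eye(3), atol=0.02)

    def test_isotropic_scale_recovery(self):
        atlas = _ellipsoid_mask()
        subject = _ellipsoid_mask(semi=(15.4, 19.8, 13.2))  # x1.1
        t = register_affine(subject, atlas)
        scales = np.linalg.norm(t.matrix[:3, :3], axis=0)
        np.testing.assert_allclose(scales, 1.1, rtol=0.02)

    def test_degenerate_mask_rejected(self):
        flat = np.zeros((10, 10, 10), bool)
        flat[5, :, :] = True
        with pytest.raises(ValueError, match="degenerate"):
            register_affine(BinaryMask(flat, np.eye(4)), _ellipsoid_mask())


class TestResample:
    def test_identity_same_grid(self, rng):
        v = Volume(rng.normal(size=(10, 10, 10)), np.eye(4))
        out = resample_to_subject(v, AffineTransform.identity(), v)
        np.testing.assert_allclose(out.data, v.data, atol=1e-6)

    def test_constant_map(self):
        v = Volume(np.full((10, 10, 10), 0.8), np.eye(4))
        out = resample_to_subject(v, AffineTransform.identity(), v)
        np.testing.assert_allclose(out.data[2:-2, 2:-2, 2:-2], 0.8, atol=1e-12)

    def test_half_voxel_shift_gives_edge_midpoint(self):
        data = np.zeros((11, 5, 5))
        data[6:, :, :] = 1.0  # step edge between index 5 and 6
        v = Volume(data, np.eye(4))
        shift = np.eye(4)
        shift[0, 3] = 0.5
        out = resample_to_subject(v, AffineTransform(shift), v)
        # target voxel 6 now samples atlas coordinate 5.5: linear midpoint
        assert out.data[6, 2, 2] == pytest.approx(0.5, abs=1e-9)


class TestWMMask:
    def test_strict_threshold(self):
        v = Volume(np.array([0.70, 0.71, 0.0]).reshape(-1, 1, 1), np.eye(4))
        m = make_wm_mask(v, 0.7)
        assert m.data.ravel().tolist() == [False, True, False]

    def test_all_zero(self):
        assert make_wm_mask(Volume(np.zeros((3, 3, 3)), np.eye(4))).n_voxels() == 0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            make_wm_mask(Volume(np.full((3, 3, 3), 1.5), np.eye(4)))


def test_flair_like_reference_subtraction():
    t2 = Volume(np.full((4, 4, 4), 2.0), np.eye(4))
    csf = Volume(np.zeros((4, 4, 4)), np.eye(4))
    csf.data[0] = 3.0
    out = make_flair_like_reference(t2, csf)
    assert (out.data[0] == 0.0).all() and (out.data[1:] == 2.0).all()


def _components(mask, connectivity=26):
    return label_components(mask, np.eye(4), 1.0, connectivity, threshold_used=0.0)


class TestWMOverlapFilter:
    def test_single_overlap_voxel_retains_whole_component(self):
        comp = np.zeros((10, 10, 10), bool)
        comp[1:6, 1:3, 1:6] = True  # 50 voxels
        wm = np.zeros((10, 10, 10), bool)
        wm[1, 1, 1] = True
        out = filter_by_wm_overlap(_components(comp), BinaryMask(wm, np.eye(4)))
        assert out.n_components == 1 and out.n_voxels() == 50

    def test_component_outside_wm_removed_and_ids_densified(self):
        comp = np.zeros((12, 6, 6), bool)
        comp[1:3, 1:3, 1:3] = True
        comp[8:10, 1:3, 1:3] = True
        wm = np.zeros((12, 6, 6), bool)
        wm[8, 1, 1] = True
        out = filter_by_wm_overlap(_components(comp), BinaryMask(wm, np.eye(4)))
        assert [c.id for c in out.components] == [1]
        assert out.n_voxels() == 8

    def test_empty_wm_mask_empty_result(self):
        comp = np.zeros((6, 6, 6), bool)
        comp[2:4, 2:4, 2:4] = True
        out = filter_by_wm_overlap(_components(comp), BinaryMask(np.zeros((6, 6, 6), bool), np.eye(4)))
        assert out.n_components == 0

    def test_idempotent(self):
        comp = np.zeros((10, 10, 10), bool)
        comp[1:4, 1:4, 1:4] = True
        wm = np.zeros((10, 10, 10), bool)
        wm[2, 2, 2] = True
        wm_m = BinaryMask(wm, np.eye(4))
        once = filter_by_wm_overlap(_components(comp), wm_m)
        twice = filter_by_wm_overlap(once, wm_m)
        np.testing.assert_array_equal(once.label_map, twice.label_map)


MIDPLANE = Plane(point=np.array([10.0, 0.0, 0.0]), normal=np.array([1.0, 0.0, 0.0]))


class TestMidlineFilter:
    def test_septum_sheet_fully_removed(self):
        sheet = np.zeros((21, 11, 11), bool)
        sheet[9:12, 2:9, 2:9] = True  # within 2 mm of plane x=10
        out = midline_filter(_components(sheet), MIDPLANE)
        assert out.n_components == 0

    def test_truncation_keeps_distal_voxels(self):
        comp = np.zeros((30, 7, 7), bool)
        comp[11:23, 2:5, 2:5] = True  # spans x=11..22, distance 1..12 mm
        out = midline_filter(_components(comp), MIDPLANE)
        assert out.n_voxels() > 0
        d = midline_distances(out, MIDPLANE)
        assert d.min() > 9.0
        # exactly the voxels beyond 9 mm survive (x = 20, 21, 22)
        assert out.n_voxels() == 3 * 3 * 3

    def test_component_at_5mm_untouched(self):
        comp = np.zeros((30, 7, 7), bool)
        comp[15:20, 2:5, 2:5] = True  # nearest voxel 5 mm from plane
        before = _components(comp)
        out = midline_filter(before, MIDPLANE)
        np.testing.assert_array_equal(out.mask, comp)

    def test_never_removes_beyond_truncation(self, rng):
        comp = rng.random((25, 9, 9)) > 0.6
        cs = _components(comp)
        out = midline_filter(cs, MIDPLANE)
        removed = cs.mask & ~out.mask
        idx = np.argwhere(removed)
        if idx.size:
            assert np.abs(idx[:, 0] - 10.0).max() <= 9.0

    def test_only_deletes_and_idempotent(self, rng):
        comp = rng.random((25, 9, 9)) > 0.7
        cs = _components(comp)
        once = midline_filter(cs, MIDPLANE)
        assert not (once.mask & ~cs.mask).any()
        twice = midline_filter(once, MIDPLANE)
        np.testing.assert_array_equal(once.mask, twice.mask)

    def test_touch_must_not_exceed_truncate(self):
        with pytest.raises(ValueError):
            midline_filter(_components(np.zeros((5, 5, 5), bool)), MIDPLANE, 10.0, 9.0)


class TestSyntheticAtlas:
    def test_bundle_properties(self, atlas):
        assert atlas.wm_prob.data.min() >= 0 and atlas.wm_prob.data.max() <= 1
        assert atlas.standard_icv_mm3 > 0
        np.testing.assert_allclose(atlas.midline_plane.normal, [1, 0, 0])
        # WM mask at 0.7 sits inside the brain
        wm = make_wm_mask(atlas.wm_prob, 0.7)
        assert wm.n_voxels() > 0
        assert not (wm.data & ~atlas.brain_mask.data).any()
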