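"""Tests for diameter extraction and voxel-count volumetry on masks."""

import numpy as np
import pytest

from pldvol.mask import (
    EmptyMaskError,
    LandmarkConfig,
    LiverMask,
    MaskError,
    basim_diameters,
    load_mask,
    qdsim_diameters,
    reference_volume,
    resample_thickness,
    save_mask,
)
from pldvol.model import basim_index, qdsim_index
from pldvol.phantom import ellipsoid_mask

from conftest import make_box_mask


# ---------------------------------------------------------------- volumes
def test_reference_volume_single_voxel():
    data = np.zeros((3, 3, 3), dtype=bool)
    data[1, 1, 1] = True
    assert reference_volume(LiverMask(data, (1, 1, 1))) == pytest.approx(0.001)


def test_reference_volume_box():
    data = np.zeros((12, 12, 12), dtype=bool)
    data[1:11, 1:11, 1:11] = True
    assert reference_volume(LiverMask(data, (1, 1, 1))) == pytest.approx(1.0)


def test_reference_volume_sphere_matches_analytic():
    m = ellipsoid_mask((20, 20, 20), (1, 1, 1))
    analytic = 4.0 / 3.0 * np.pi * 20**3 / 1000.0
    assert reference_volume(m) == pytest.approx(analytic, rel=0.02)


def test_empty_mask_raises():
    empty = LiverMask(np.zeros((4, 4, 4), dtype=bool), (1, 1, 1))
    with pytest.raises(EmptyMaskError):
        reference_volume(empty)
    with pytest.raises(EmptyMaskError):
        basim_diameters(empty)
    with pytest.raises(EmptyMaskError):
        qdsim_diameters(empty)


# ---------------------------------------------------------------- BASiM
def test_basim_box_extents(box_mask):
    d = basim_diameters(box_mask)
    assert (d.cc, d.ap, d.ml) == (20.0, 15.0, 12.0)
    assert d.slice_thickness_mm == 5.0


def test_basim_posterior_landmark_extends_ap(box_mask):
    # dorsal face of the box sits at y = 5 voxels × 1 mm
    lm = LandmarkConfig(posterior_landmark_mm=5.0 - 30.0)
    d = basim_diameters(box_mask, lm)
    assert d.ap == pytest.approx(18.0)
    # landmark offset moves AP by exactly the offset
    lm2 = LandmarkConfig(posterior_landmark_mm=5.0 - 42.0)
    assert basim_diameters(box_mask, lm2).ap == pytest.approx(d.ap + 1.2)


def test_basim_landmark_anterior_to_liver_rejected(box_mask):
    with pytest.raises(MaskError, match="landmark"):
        basim_diameters(box_mask, LandmarkConfig(posterior_landmark_mm=1000.0))


def test_basim_ellipsoid_extents_within_one_voxel():
    m = ellipsoid_mask((60, 75, 120), (2.0, 2.0, 4.0))
    d = basim_diameters(m)
    assert d.cc == pytest.approx(24.0, abs=0.4)
    assert d.ap == pytest.approx(15.0, abs=0.2)
    assert d.ml == pytest.approx(12.0, abs=0.2)


def test_translation_invariance(box_mask):
    d0 = basim_diameters(box_mask)
    q0 = qdsim_diameters(box_mask)
    shifted = LiverMask(np.roll(box_mask.data, (3, 2, 1), axis=(0, 1, 2)), box_mask.spacing)
    d1 = basim_diameters(shifted)
    assert (d1.cc, d1.ap, d1.ml) == (d0.cc, d0.ap, d0.ml)
    # midline fixed relative to the object keeps QDSiM invariant too
    nx = box_mask.data.shape[0]
    q1 = qdsim_diameters(shifted, LandmarkConfig(midline=nx / 2 + 3))
    assert (q1.lcc, q1.lap, q1.rcc, q1.rap, q1.ml) == (q0.lcc, q0.lap, q0.rcc, q0.rap, q0.ml)


# ---------------------------------------------------------------- QDSiM
def test_qdsim_symmetric_box_splits_evenly(box_mask):
    q = qdsim_diameters(box_mask)
    assert (q.lcc, q.rcc) == (20.0, 20.0)
    assert (q.lap, q.rap) == (15.0, 15.0)
    assert q.ml == 12.0


def test_qdsim_two_disjoint_boxes():
    # left box 80×100×100 mm, right box 120×150×200 mm, 20 mm gap at the midline
    data = np.zeros((240, 160, 44), dtype=bool)
    data[10:90, 10:110, 2:22] = True     # left: 80 × 100 × 100 (dz=5)
    data[110:230, 5:155, 2:42] = True    # right: 120 × 150 × 200
    m = LiverMask(data, (1.0, 1.0, 5.0))
    q = qdsim_diameters(m, LandmarkConfig(midline=100.0))
    assert (q.lcc, q.lap) == (10.0, 10.0)
    assert (q.rcc, q.rap) == (20.0, 15.0)
    # max transverse extent spans both boxes where they coexist
    assert q.ml == pytest.approx((230 - 10) / 10.0)


def test_qdsim_degenerate_side(caplog):
    data = np.zeros((60, 40, 20), dtype=bool)
    data[40:55, 10:30, 5:15] = True  # entirely right of midline 30
    m = LiverMask(data, (1.0, 1.0, 5.0))
    with caplog.at_level("WARNING"):
        q = qdsim_diameters(m)
    assert (q.lcc, q.lap) == (0.0, 0.0)
    assert qdsim_index(q) == pytest.approx(q.rcc * q.rap * q.ml / 2)
    assert any("left" in r.message for r in caplog.records)


def test_qdsim_mirror_swaps_sides():
    m = make_box_mask(margin=(5, 5, 2))
    # asymmetric: carve away part of the right half
    data = m.data.copy()
    data[90:, :, 30:] = False
    m = LiverMask(data, m.spacing)
    q = qdsim_diameters(m)
    mirrored = LiverMask(np.flip(m.data, axis=0).copy(), m.spacing)
    qm = qdsim_diameters(mirrored)
    assert (qm.lcc, qm.lap) == (q.rcc, q.rap)
    assert (qm.rcc, qm.rap) == (q.lcc, q.lap)
    assert qm.ml == q.ml
    assert qdsim_index(qm) == pytest.approx(qdsim_index(q))


def test_bounding_product_dominates_reference_volume(box_mask):
    # global-extent product (cm³) is an upper envelope of the voxel volume (mL)
    d = basim_diameters(box_mask)
    assert basim_index(d) >= reference_volume(box_mask) - 1e-9


# ---------------------------------------------------------------- resampling
def test_resample_identity(box_mask):
    m = resample_thickness(box_mask, 5.0)
    assert np.array_equal(m.data, box_mask.data)
    assert m.spacing == box_mask.spacing


def test_resample_box_cc_within_one_slice():
    m3 = make_box_mask(spacing=(2.0, 2.0, 3.0), margin=(2, 2, 2))
    m5 = resample_thickness(m3, 5.0)
    cc3 = basim_diameters(m3).cc
    cc5 = basim_diameters(m5).cc
    assert abs(cc5 - cc3) <= 0.5
    assert abs(reference_volume(m5) - reference_volume(m3)) <= m3.data.shape[0] * m3.data.shape[1] * 2 * 2 * 5 / 1000.0


def test_resample_ellipsoid_volume_preserved():
    fine = ellipsoid_mask((30, 35, 40), (1.0, 1.0, 1.0))
    coarse = resample_thickness(fine, 5.0)
    assert reference_volume(coarse) == pytest.approx(reference_volume(fine), rel=0.03)


def test_resample_finer_requires_interpolation_flag(box_mask):
    with pytest.raises(MaskError, match="interpolate"):
        resample_thickness(box_mask, 3.0)
    m = resample_thickness(box_mask, 3.0, interpolate=True)
    assert m.spacing[2] == 3.0
    assert reference_volume(m) == pytest.approx(reference_volume(box_mask), rel=0.05)


# ---------------------------------------------------------------- NIfTI I/O
def test_nifti_round_trip(tmp_path, box_mask):
    p = tmp_path / "box.nii.gz"
    save_mask(box_mask, p)
    m = load_mask(p)
    assert np.array_equal(m.data, box_mask.data)
    assert m.spacing == box_mask.spacing


def test_load_reorients_flipped_volume(tmp_path, box_mask):
    import nibabel as nib

    # write the same object in an LPS-flavoured orientation
    flipped = np.flip(box_mask.data, axis=(0, 1)).astype(np.uint8)
    nx, ny = flipped.shape[:2]
    affine = np.diag([-1.0, -1.0, 5.0, 1.0])
    affine[0, 3] = nx - 1.0
    affine[1, 3] = ny - 1.0
    nib.save(nib.Nifti1Image(flipped, affine), tmp_path / "lps.nii.gz")
    m = load_mask(tmp_path / "lps.nii.gz")
    assert np.array_equal(m.data, box_mask.data)
    d = basim_diameters(m)
    assert (d.cc, d.ap, d.ml) == (20.0, 15.0, 12.0)
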