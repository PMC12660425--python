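"""Tests for the synthetic cystic-liver generator and assessor simulation."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from pldvol.agreement import icc_2_1
from pldvol.mask import basim_diameters, reference_volume
from pldvol.model import DiameterSetBASiM, DiameterSetQDSiM, basim_index, calibrate
from pldvol.phantom import (
    AssessorModel,
    Ellipsoid,
    PhantomSpec,
    _fill_ellipsoid,
    ellipsoid_mask,
    make_cohort,
    make_phantom,
    simulate_assessor,
)

from conftest import SMALL_SPEC


def test_sphere_phantom_volume_matches_analytic():
    m = ellipsoid_mask((20, 20, 20), (1, 1, 1))
    assert reference_volume(m) == pytest.approx(4 / 3 * np.pi * 20**3 / 1000, rel=0.02)


def test_make_phantom_deterministic():
    spec = dataclasses.replace(SMALL_SPEC, seed=13)
    m1, gt1 = make_phantom(spec)
    m2, gt2 = make_phantom(spec)
    assert np.array_equal(m1.data, m2.data)
    assert gt1 == gt2


def test_make_phantom_seed_changes_mask():
    m1, _ = make_phantom(dataclasses.replace(SMALL_SPEC, seed=1))
    m2, _ = make_phantom(dataclasses.replace(SMALL_SPEC, seed=2))
    assert not np.array_equal(m1.data, m2.data)


def test_disjoint_lobes_add():
    spec = dataclasses.replace(SMALL_SPEC, n_cysts=0, deform_jitter=0.0)
    m, gt = make_phantom(spec)
    a = np.zeros(spec.grid_shape, dtype=bool)
    b = np.zeros(spec.grid_shape, dtype=bool)
    _fill_ellipsoid(a, spec.spacing, spec.right_lobe.center_mm, spec.right_lobe.semi_axes_mm)
    _fill_ellipsoid(b, spec.spacing, spec.left_lobe.center_mm, spec.left_lobe.semi_axes_mm)
    overlap = int((a & b).sum())
    vox = spec.spacing[0] * spec.spacing[1] * spec.spacing[2] / 1000.0
    assert gt == pytest.approx((int(a.sum()) + int(b.sum()) - overlap) * vox)


def test_lobe_outside_grid_rejected():
    spec = dataclasses.replace(SMALL_SPEC, volume_scale=8.0)  # 2× linear
    with pytest.raises(ValueError, match="outside the grid"):
        make_phantom(spec)


def test_right_lobe_must_dominate():
    with pytest.raises(ValueError, match="right lobe"):
        PhantomSpec(
            right_lobe=Ellipsoid((100, 100, 100), (40, 40, 40)),
            left_lobe=Ellipsoid((200, 100, 100), (60, 60, 60)),
        )


def test_volume_scale_rescales_volume():
    m1, gt1 = make_phantom(dataclasses.replace(SMALL_SPEC, seed=5))
    m2, gt2 = make_phantom(dataclasses.replace(SMALL_SPEC, seed=5, volume_scale=0.8))
    assert gt2 / gt1 == pytest.approx(0.8, abs=0.01)


# ---------------------------------------------------------------- assessors
def test_zero_noise_assessor_is_identity():
    model = AssessorModel(0.0, 0.0, 0.0)
    d = DiameterSetBASiM(cc=24.0, ap=15.0, ml=12.0, slice_thickness_mm=3.0)
    assert simulate_assessor(d, model) == d
    q = DiameterSetQDSiM(lcc=10.0, lap=9.0, rcc=20.0, rap=15.0, ml=22.0, slice_thickness_mm=3.0)
    assert simulate_assessor(q, model) == q


def test_ap_bias_inflates_index_linearly():
    model = AssessorModel(diameter_sd_cm=0.0, slice_jitter_sd=0.0, bias_cm={"ap": 0.5})
    d = DiameterSetBASiM(cc=24.0, ap=15.0, ml=12.0, slice_thickness_mm=3.0)
    noisy = simulate_assessor(d, model)
    assert basim_index(noisy) / basim_index(d) == pytest.approx((15.0 + 0.5) / 15.0)


def test_cc_jitter_stays_slice_multiple():
    model = AssessorModel(diameter_sd_cm=0.0, slice_jitter_sd=2.0)
    d = DiameterSetBASiM(cc=24.0, ap=15.0, ml=12.0, slice_thickness_mm=3.0)
    rng = np.random.default_rng(0)
    for _ in range(20):
        noisy = simulate_assessor(d, model, rng)
        n = noisy.cc / 0.3
        assert abs(n - round(n)) < 1e-9


def test_two_noisy_assessors_agree_on_calibrated_volumes():
    """σ = 0.3 cm per diameter over 50 phantoms of varying size → ICC > 0.95."""
    model = AssessorModel(diameter_sd_cm=0.3, slice_jitter_sd=0.5)
    rng = np.random.default_rng(17)
    vols = {"A": [], "B": []}
    for i in range(50):
        scale = float(np.exp(rng.normal(0.0, 0.25)))
        spec = dataclasses.replace(SMALL_SPEC, seed=100 + i, volume_scale=scale)
        m, _ = make_phantom(spec)
        true_d = basim_diameters(m)
        for a in ("A", "B"):
            d = simulate_assessor(true_d, model, rng)
            vols[a].append(calibrate(basim_index(d), "basim"))
    res = icc_2_1(np.column_stack([vols["A"], vols["B"]]))
    assert res.icc > 0.95


# ---------------------------------------------------------------- cohorts
def test_cohort_shapes_and_schema():
    tab, truth = make_cohort(
        3, base_spec=SMALL_SPEC, timepoints=("baseline", "week24"), seed=4
    )
    assert len(tab) == 3 * 2 * 2  # cases × timepoints × assessors
    assert set(tab.columns) >= {"case_id", "timepoint", "assessor", "cc", "ap", "ml", "lcc", "reference_volume_ml"}
    assert len(truth) == 3 * 2
    assert (tab.groupby(["case_id", "timepoint", "assessor"]).size() == 1).all()


def test_cohort_zero_shrink_keeps_masks_identical():
    _, truth = make_cohort(
        2,
        shrink_mean=0.0,
        shrink_sd=0.0,
        base_spec=SMALL_SPEC,
        timepoints=("baseline", "week24"),
        assessor_model=AssessorModel(0.0, 0.0, 0.0),
        seed=8,
    )
    assert (truth[truth.timepoint == "week24"]["realized_rate_pct"] == 0.0).all()


def test_cohort_fixed_shrink_recovers_rate():
    _, truth = make_cohort(
        4,
        shrink_mean=-6.05,
        shrink_sd=0.0,
        base_spec=SMALL_SPEC,
        timepoints=("baseline", "week24"),
        assessor_model=AssessorModel(0.0, 0.0, 0.0),
        seed=8,
    )
    realized = truth[truth.timepoint == "week24"]["realized_rate_pct"].to_numpy()
    assert realized == pytest.approx(-6.05, abs=0.5)  # coarse-grid voxelization


def test_cohort_mean_rate_within_its_own_ci():
    """The t-CI on the estimated mean rate covers the design mean in ≥90% of runs."""
    from pldvol.agreement import cohort_change_summary

    hits = 0
    runs = 100
    for r in range(runs):
        _, truth = make_cohort(
            6,
            shrink_mean=-6.05,
            shrink_sd=6.0,
            base_spec=SMALL_SPEC,
            timepoints=("baseline", "week24"),
            assessor_model=AssessorModel(0.0, 0.0, 0.0),
            seed=1000 + r,
        )
        rates = truth[truth.timepoint == "week24"]["realized_rate_pct"]
        mean, (lo, hi) = cohort_change_summary(rates)
        if lo <= -6.05 <= hi:
            hits += 1
    assert hits >= 90


def test_calibration_factor_band_for_default_family():
    """Index/reference ratio sits between the ellipsoid bound π/6⁻¹≈1.91 and ~3."""
    ratios = []
    for i in range(8):
        spec = dataclasses.replace(SMALL_SPEC, seed=200 + i)
        m, gt = make_phantom(spec)
        ratios.append(basim_index(basim_diameters(m)) / gt)
    ratios = np.array(ratios)
    assert ratios.min() > 1.9
    assert ratios.max() < 3.1
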