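"""Synthetic cystic-liver phantoms with known ground-truth volume.

A phantom is the union of two lobe ellipsoids (the right lobe larger than
the left, as in a liver) decorated with spherical surface bumps standing
in for exophytic cysts, voxelized on a regular grid. The construction is
fully analytic, so ground truth is the voxel-count volume of the realized
mask and every linear dimension is known by design. Phantoms are
deterministic given their spec and seed.

On top of single phantoms, :func:`simulate_assessor` adds measurement
noise (per-diameter Gaussian error, whole-slice jitter for the slice-count
diameters, optional bias) to emulate independent human assessors, and
:func:`make_cohort` builds a longitudinal cohort — baseline, 24 weeks
post-treatment, follow-up — where each post-treatment liver is the same
geometry uniformly rescaled by a drawn volume-change rate. This yields
measurement tables with known per-case change rates, so the whole
measurement → index → calibration → agreement pipeline can be exercised
without clinical data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import mask as mask_mod
from .model import DiameterSetBASiM, DiameterSetQDSiM
from .mask import LandmarkConfig, LiverMask

logger = logging.getLogger(__name__)

__all__ = [
    "Ellipsoid",
    "PhantomSpec",
    "AssessorModel",
    "ellipsoid_mask",
    "make_phantom",
    "simulate_assessor",
    "make_cohort",
]

_MIN_DIAMETER_CM = 0.1  # positive floor for noisy diameters


@dataclass(frozen=True)
class Ellipsoid:
    """Axis-aligned ellipsoid: center and semi-axes in mm (grid coords)."""

    center_mm: tuple
    semi_axes_mm: tuple


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic cystic liver.

    Geometry is expressed in physical mm on the canonical axes (axis 0
    left→right, axis 1 posterior→anterior, axis 2 inferior→superior).
    Defaults emulate an enlarged polycystic liver of roughly 6.5 L with a
    ~29 cm transverse and ~28 cm cranio-caudal extent, voxelized at
    1×1 mm in plane (clinical CT pixel spacing is sub-millimetre) with
    3 mm axial slices. ``volume_scale`` rescales all linear
    dimensions by its cube root about the grid center, so the same seed
    produces the same liver at a different volume — this is how uniform
    growth/shrinkage between timepoints is realized.
    """

    grid_shape: tuple = (440, 280, 160)
    spacing: tuple = (1.0, 1.0, 3.0)
    right_lobe: Ellipsoid = field(
        default_factory=lambda: Ellipsoid((290.0, 140.0, 245.0), (80.0, 85.0, 140.0))
    )
    left_lobe: Ellipsoid = field(
        default_factory=lambda: Ellipsoid((150.0, 135.0, 230.0), (72.0, 75.0, 110.0))
    )
    n_cysts: int = 12
    cyst_radius_mm: tuple = (8.0, 28.0)
    cyst_left_fraction: float = 0.6  # cyst burden biased to the left lobe
    deform_jitter: float = 0.08  # anisotropic semi-axis jitter (SD, fraction)
    volume_scale: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(r < l for r, l in zip(self.right_lobe.semi_axes_mm, self.left_lobe.semi_axes_mm)):
            raise ValueError("right lobe semi-axes must dominate the left lobe's")
        if self.volume_scale <= 0:
            raise ValueError("volume_scale must be positive")
        if self.n_cysts < 0 or self.cyst_radius_mm[0] > self.cyst_radius_mm[1]:
            raise ValueError("invalid cyst parameters")


@dataclass(frozen=True)
class AssessorModel:
    """Measurement-noise model for one human assessor.

    diameter_sd_cm : Gaussian SD added to each continuous diameter (cm).
    slice_jitter_sd : SD, in whole slices, of the slice-count error for the
        cranio-caudal diameters (kept an integer number of slices so the
        slice-multiple invariant survives).
    bias_cm : systematic offset added to continuous diameters; either a
        scalar applied to all, or a mapping like ``{"ap": 0.5}``.
    """

    diameter_sd_cm: float = 0.3
    slice_jitter_sd: float = 0.5
    bias_cm: object = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.diameter_sd_cm < 0 or self.slice_jitter_sd < 0:
            raise ValueError("noise SDs must be non-negative")

    def bias_for(self, name: str) -> float:
        if isinstance(self.bias_cm, dict):
            return float(self.bias_cm.get(name, 0.0))
        return float(self.bias_cm)


def _fill_ellipsoid(data: np.ndarray, spacing, center, semi) -> None:
    """OR an ellipsoid into ``data`` using voxel-center membership."""
    shape = data.shape
    lo, hi = [], []
    for ax in range(3):
        d = spacing[ax]
        lo.append(max(0, int(np.floor((center[ax] - semi[ax]) / d - 0.5))))
        hi.append(min(shape[ax], int(np.ceil((center[ax] + semi[ax]) / d + 0.5)) + 1))
    if any(l >= h for l, h in zip(lo, hi)):
        return
    ix = (np.arange(lo[0], hi[0]) + 0.5) * spacing[0]
    iy = (np.arange(lo[1], hi[1]) + 0.5) * spacing[1]
    iz = (np.arange(lo[2], hi[2]) + 0.5) * spacing[2]
    q = (
        ((ix[:, None, None] - center[0]) / semi[0]) ** 2
        + ((iy[None, :, None] - center[1]) / semi[1]) ** 2
        + ((iz[None, None, :] - center[2]) / semi[2]) ** 2
    )
    data[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] |= q <= 1.0


def ellipsoid_mask(semi_axes_mm, spacing=(1.0, 1.0, 1.0), margin_mm: float = 2.0) -> LiverMask:
    """Digitize a single centered axis-aligned ellipsoid (test workhorse)."""
    semi = np.asarray(semi_axes_mm, dtype=float)
    spacing = tuple(float(s) for s in spacing)
    shape = tuple(int(np.ceil(2 * (a + margin_mm) / d)) for a, d in zip(semi, spacing))
    center = tuple(s * d / 2.0 for s, d in zip(shape, spacing))
    data = np.zeros(shape, dtype=bool)
    _fill_ellipsoid(data, spacing, center, semi)
    return LiverMask(data, spacing)


def _realized_geometry(spec: PhantomSpec):
    """Lobes and cysts after jitter, placement and volume scaling."""
    rng = np.random.default_rng(spec.seed)
    lobes = []
    for lobe in (spec.right_lobe, spec.left_lobe):
        jit = np.clip(1.0 + spec.deform_jitter * rng.standard_normal(3), 0.85, 1.18)
        lobes.append(Ellipsoid(lobe.center_mm, tuple(np.asarray(lobe.semi_axes_mm) * jit)))
    right, left = lobes

    spheres = []
    for _ in range(spec.n_cysts):
        host = left if rng.random() < spec.cyst_left_fraction else right
        u = rng.standard_normal(3)
        u /= np.linalg.norm(u)
        c = np.asarray(host.center_mm) + u * np.asarray(host.semi_axes_mm)
        r = rng.uniform(*spec.cyst_radius_mm)
        spheres.append((tuple(c), r))

    s = spec.volume_scale ** (1.0 / 3.0)
    anchor = np.array(
        [n * d / 2.0 for n, d in zip(spec.grid_shape, spec.spacing)]
    )

    def scale_pt(p):
        return tuple(anchor + (np.asarray(p) - anchor) * s)

    right = Ellipsoid(scale_pt(right.center_mm), tuple(np.asarray(right.semi_axes_mm) * s))
    left = Ellipsoid(scale_pt(left.center_mm), tuple(np.asarray(left.semi_axes_mm) * s))
    spheres = [(scale_pt(c), r * s) for c, r in spheres]
    return right, left, spheres


def make_phantom(spec: PhantomSpec) -> tuple:
    """Voxelize a phantom; returns ``(LiverMask, ground_truth_volume_mL)``.

    Ground truth is the voxel-count volume of the realized mask (exact for
    the digitized object). Both lobes must fit inside the grid.
    """
    right, left, spheres = _realized_geometry(spec)
    extent = np.array([n * d for n, d in zip(spec.grid_shape, spec.spacing)])
    for lobe in (right, left):
        c, a = np.asarray(lobe.center_mm), np.asarray(lobe.semi_axes_mm)
        if np.any(c - a < 0) or np.any(c + a > extent):
            raise ValueError(
                f"lobe (center {tuple(np.round(c,1))}, semi-axes {tuple(np.round(a,1))}) "
                f"extends outside the grid {tuple(extent)} mm"
            )
    data = np.zeros(spec.grid_shape, dtype=bool)
    _fill_ellipsoid(data, spec.spacing, right.center_mm, right.semi_axes_mm)
    _fill_ellipsoid(data, spec.spacing, left.center_mm, left.semi_axes_mm)
    for c, r in spheres:
        _fill_ellipsoid(data, spec.spacing, c, (r, r, r))
    m = LiverMask(data, spec.spacing)
    return m, mask_mod.reference_volume(m)


def _jitter_cc(name: str, cc: float, thickness_mm: Optional[float], model: AssessorModel, rng) -> float:
    if thickness_mm is None:
        return _noisy(name, cc, model, rng)
    step = thickness_mm / 10.0
    k = int(round(rng.normal(0.0, model.slice_jitter_sd))) if model.slice_jitter_sd > 0 else 0
    return max(step, cc + k * step)


def _noisy(name: str, value: float, model: AssessorModel, rng) -> float:
    if value == 0:
        return 0.0  # a degenerate side stays degenerate
    noise = rng.normal(0, model.diameter_sd_cm) if model.diameter_sd_cm > 0 else 0.0
    return max(_MIN_DIAMETER_CM, value + model.bias_for(name) + noise)


def simulate_assessor(true_d, model: AssessorModel, rng=None):
    """Apply an assessor's noise model to a true diameter set.

    Zero noise and zero bias reproduce the input exactly. Cranio-caudal
    diameters are jittered in whole slices; the others get Gaussian error
    plus bias, floored at a small positive value.
    """
    if rng is None:
        rng = np.random.default_rng(model.seed)
    if isinstance(true_d, DiameterSetBASiM):
        return DiameterSetBASiM(
            cc=_jitter_cc("cc", true_d.cc, true_d.slice_thickness_mm, model, rng),
            ap=_noisy("ap", true_d.ap, model, rng),
            ml=_noisy("ml", true_d.ml, model, rng),
            slice_thickness_mm=true_d.slice_thickness_mm,
        )
    if isinstance(true_d, DiameterSetQDSiM):
        return DiameterSetQDSiM(
            lcc=_jitter_cc("lcc", true_d.lcc, true_d.slice_thickness_mm, model, rng) if true_d.lcc else 0.0,
            lap=_noisy("lap", true_d.lap, model, rng),
            rcc=_jitter_cc("rcc", true_d.rcc, true_d.slice_thickness_mm, model, rng) if true_d.rcc else 0.0,
            rap=_noisy("rap", true_d.rap, model, rng),
            ml=_noisy("ml", true_d.ml, model, rng),
            slice_thickness_mm=true_d.slice_thickness_mm,
        )
    raise TypeError(f"unsupported diameter set type {type(true_d)!r}")


_ASSESSOR_NAMES = "ABCDEFGH"


def make_cohort(
    n_cases: int = 26,
    *,
    shrink_mean: float = -6.05,
    shrink_sd: float = 8.0,
    followup_mean: float = -3.35,
    followup_sd: float = 12.0,
    base_spec: PhantomSpec | None = None,
    assessor_model: AssessorModel | None = None,
    n_assessors: int = 2,
    timepoints: Sequence[str] = ("baseline", "week24", "followup"),
    baseline_volume_log_sd: float = 0.30,
    landmark: LandmarkConfig | None = None,
    seed: int = 0,
) -> tuple:
    """Simulate a longitudinal treatment cohort.

    Each case is a phantom whose baseline size varies lognormally across
    the cohort; the week-24 and follow-up livers are the same geometry
    uniformly rescaled by drawn change rates r ~ N(mean, sd) percent
    relative to baseline (non-physical draws with 1 + r/100 ≤ 0 are
    resampled and logged). Every timepoint is measured with BASiM and
    QDSiM by ``n_assessors`` independent noisy assessors; the voxel-count
    reference volume plays the role of semi-automatic volumetry.

    Returns ``(measurements, truth)``: a measurement table in the
    canonical CSV schema and a per-case/timepoint truth table with
    ground-truth volumes, drawn rates and realized (voxel) rates.
    """
    if n_cases < 2:
        raise ValueError("need at least 2 cases")
    if base_spec is None:
        base_spec = PhantomSpec()
    if assessor_model is None:
        assessor_model = AssessorModel()
    if n_assessors < 1 or n_assessors > len(_ASSESSOR_NAMES):
        raise ValueError(f"n_assessors must be in 1..{len(_ASSESSOR_NAMES)}")
    unknown = set(timepoints) - {"baseline", "week24", "followup"}
    if unknown or "baseline" not in timepoints:
        raise ValueError(f"timepoints must be drawn from baseline/week24/followup and include baseline, got {timepoints}")

    rate_params = {"week24": (shrink_mean, shrink_sd), "followup": (followup_mean, followup_sd)}
    rows, truth_rows = [], []
    for i in range(n_cases):
        case_id = f"case{i:03d}"
        case_rng = np.random.default_rng([seed, i])
        geom_seed = int(case_rng.integers(2**31))
        base_scale = float(np.clip(np.exp(case_rng.normal(0.0, baseline_volume_log_sd)), 0.55, 1.85))

        rates = {}
        for tp in timepoints:
            if tp == "baseline":
                continue
            mu, sd = rate_params[tp]
            r = case_rng.normal(mu, sd)
            while 1.0 + r / 100.0 <= 0.05:
                logger.info("%s %s: resampling non-physical change rate %.1f%%", case_id, tp, r)
                r = case_rng.normal(mu, sd)
            rates[tp] = float(r)

        gt_by_tp = {}
        for t_idx, tp in enumerate(timepoints):
            factor = base_scale * (1.0 + rates.get(tp, 0.0) / 100.0)
            if not 0.4 <= factor <= 2.2:
                logger.info("%s %s: clamping extreme volume factor %.2f", case_id, tp, factor)
                factor = float(np.clip(factor, 0.4, 2.2))
            spec_tp = replace(base_spec, seed=geom_seed, volume_scale=factor)
            m, gt = make_phantom(spec_tp)
            gt_by_tp[tp] = gt
            td_b = mask_mod.basim_diameters(m, landmark)
            td_q = mask_mod.qdsim_diameters(m, landmark)
            for j in range(n_assessors):
                arng = np.random.default_rng([seed, i, t_idx, j])
                db = simulate_assessor(td_b, assessor_model, arng)
                dq = simulate_assessor(td_q, assessor_model, arng)
                rows.append(
                    {
                        "case_id": case_id,
                        "timepoint": tp,
                        "assessor": _ASSESSOR_NAMES[j],
                        "slice_thickness_mm": base_spec.spacing[2],
                        "cc": db.cc,
                        "ap": db.ap,
                        "ml": db.ml,
                        "lcc": dq.lcc,
                        "rcc": dq.rcc,
                        "lap": dq.lap,
                        "rap": dq.rap,
                        "ml_qdsim": dq.ml,
                        "reference_volume_ml": gt,
                    }
                )
            truth_rows.append(
                {
                    "case_id": case_id,
                    "timepoint": tp,
                    "volume_scale": factor,
                    "gt_volume_ml": gt,
                    "true_rate_pct": rates.get(tp, 0.0) if tp != "baseline" else np.nan,
                }
            )
        for tr in truth_rows[-len(timepoints):]:
            if tr["timepoint"] != "baseline":
                tr["realized_rate_pct"] = (
                    (tr["gt_volume_ml"] - gt_by_tp["baseline"]) / gt_by_tp["baseline"] * 100.0
                )
            else:
                tr["realized_rate_pct"] = np.nan
    measurements = pd.DataFrame(rows)
    truth = pd.DataFrame(truth_rows)
    return measurements, truth
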