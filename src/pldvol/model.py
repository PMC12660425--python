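"""Volume-index formulas for simplified CT liver volumetry.

Two linear-dimension proxies for total liver volume in polycystic liver
disease, both read off axial CT series:

* **BASiM** (bi-axial simplified measurement): a single bounding product
  ``CC × AP × ML`` of the cranio-caudal, anterior–posterior and
  medial–lateral liver diameters. AP and ML are taken on the same axial
  slice (the one where the liver protrudes most ventrally); CC is the
  number of liver-containing slices times the slice thickness.
* **QDSiM** (quadri-dimensional simplified measurement): the liver is split
  at the body midline and each side contributes half an ellipsoid-style
  box, ``(CC_side × AP_side × ML) / 2``; ML is measured on the slice of
  maximal whole-liver transverse diameter.

Raw indices are in cm³ and systematically overshoot the true volume; they
are calibrated to millilitres either by a fixed divisor (÷3 for BASiM,
÷2 for QDSiM) or by a fitted regression slope (×0.346 / ×0.497).
All diameters are stored in cm, volumes in cm³ ≡ mL; slice thickness is
given in mm and converted once at ingestion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

__all__ = [
    "DiameterSetBASiM",
    "DiameterSetQDSiM",
    "CalibrationConfig",
    "VolumeEstimate",
    "CaseRecord",
    "basim_index",
    "qdsim_index",
    "calibrate",
    "change_rate",
    "TIMEPOINTS",
]

#: Canonical timepoint vocabulary for longitudinal records.
TIMEPOINTS = ("baseline", "week24", "followup")


def _require_finite_positive(name: str, value: float, *, allow_zero: bool = False) -> None:
    if not math.isfinite(value):
        raise ValueError(f"{name} must be finite, got {value!r}")
    if allow_zero:
        if value < 0:
            raise ValueError(f"{name} must be non-negative, got {value!r}")
    elif value <= 0:
        raise ValueError(f"{name} must be strictly positive, got {value!r}")


@dataclass(frozen=True)
class DiameterSetBASiM:
    """The three BASiM diameters, in cm.

    Parameters
    ----------
    cc : float
        Cranio-caudal diameter: liver-containing slice count × slice
        thickness.
    ap : float
        Anterior–posterior diameter on the most-ventral slice, measured to
        the posterior landmark (spine) or to the posterior liver surface.
    ml : float
        Maximum transverse diameter on the *same* slice as ``ap``.
    slice_thickness_mm : float, optional
        Axial slice thickness used to derive ``cc``. When given, ``cc``
        must be an integer multiple of it (after mm→cm conversion).
    """

    cc: float
    ap: float
    ml: float
    slice_thickness_mm: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("cc", "ap", "ml"):
            _require_finite_positive(name, getattr(self, name))
        if self.slice_thickness_mm is not None:
            _require_finite_positive("slice_thickness_mm", self.slice_thickness_mm)
            n = self.cc / (self.slice_thickness_mm / 10.0)
            if abs(n - round(n)) > 1e-6 * max(1.0, abs(n)):
                raise ValueError(
                    f"cc={self.cc} cm is not an integer multiple of the slice "
                    f"thickness {self.slice_thickness_mm} mm"
                )


@dataclass(frozen=True)
class DiameterSetQDSiM:
    """The five QDSiM diameters, in cm.

    ``lcc``/``rcc`` and ``lap``/``rap`` are the per-side cranio-caudal and
    anterior–posterior diameters; ``ml`` is the maximum transverse diameter
    over all slices (a distinct quantity from BASiM's same-slice ML).
    A side that contains no liver may have both of its diameters zero, in
    which case the index degrades to the other side's term.
    """

    lcc: float
    lap: float
    rcc: float
    rap: float
    ml: float
    slice_thickness_mm: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("lcc", "lap", "rcc", "rap"):
            _require_finite_positive(name, getattr(self, name), allow_zero=True)
        _require_finite_positive("ml", self.ml)
        if self.slice_thickness_mm is not None:
            _require_finite_positive("slice_thickness_mm", self.slice_thickness_mm)
        left_empty = self.lcc == 0 or self.lap == 0
        right_empty = self.rcc == 0 or self.rap == 0
        if left_empty and right_empty:
            raise ValueError("at least one side must have positive cc and ap diameters")


@dataclass(frozen=True)
class CalibrationConfig:
    """How a raw volume index (cm³) maps to a calibrated volume (mL).

    ``divisor`` mode applies the fixed divisors (BASiM ÷3, QDSiM ÷2);
    ``regression`` mode applies the fitted slopes of reference volume on
    index (BASiM ×0.346, QDSiM ×0.497).
    """

    basim_divisor: float = 3.0
    qdsim_divisor: float = 2.0
    basim_regression_coeff: float = 0.346
    qdsim_regression_coeff: float = 0.497
    mode: str = "divisor"

    def __post_init__(self) -> None:
        for name in (
            "basim_divisor",
            "qdsim_divisor",
            "basim_regression_coeff",
            "qdsim_regression_coeff",
        ):
            _require_finite_positive(name, getattr(self, name))
        if self.mode not in ("divisor", "regression"):
            raise ValueError(f"mode must be 'divisor' or 'regression', got {self.mode!r}")

    def factor(self, method: str) -> float:
        """Multiplicative factor mapping index → calibrated volume."""
        method = method.lower()
        if method == "basim":
            return 1.0 / self.basim_divisor if self.mode == "divisor" else self.basim_regression_coeff
        if method == "qdsim":
            return 1.0 / self.qdsim_divisor if self.mode == "divisor" else self.qdsim_regression_coeff
        raise ValueError(f"unknown method {method!r}; expected 'basim' or 'qdsim'")


@dataclass(frozen=True)
class VolumeEstimate:
    """A volume measurement: raw index (cm³) plus calibrated volume (mL)."""

    method: str  # 'basim' | 'qdsim' | 'reference'
    index: float
    calibrated: float


@dataclass
class CaseRecord:
    """One patient × timepoint × assessor measurement record."""

    case_id: str
    timepoint: str
    assessor: str
    basim: Optional[DiameterSetBASiM] = None
    qdsim: Optional[DiameterSetQDSiM] = None
    estimates: list = field(default_factory=list)
    reference_volume_ml: Optional[float] = None

    def __post_init__(self) -> None:
        if self.timepoint not in TIMEPOINTS:
            raise ValueError(f"timepoint must be one of {TIMEPOINTS}, got {self.timepoint!r}")


def basim_index(d: DiameterSetBASiM) -> float:
    """BASiM liver volume index CC × AP × ML, in cm³.

    Scales cubically under a uniform rescaling of all three diameters.
    """
    return d.cc * d.ap * d.ml


def qdsim_index(d: DiameterSetQDSiM) -> float:
    """QDSiM liver volume index, in cm³.

    Sum of the left and right side indices, each ``cc·ap·ml / 2``. When
    both sides share their dimensions this collapses to the single box
    product ``cc·ap·ml``.
    """
    left = d.lcc * d.lap * d.ml / 2.0
    right = d.rcc * d.rap * d.ml / 2.0
    return left + right


def calibrate(index: float, method: str, cfg: CalibrationConfig | None = None) -> float:
    """Map a raw volume index (cm³) to a calibrated liver volume (mL).

    The map is linear and order preserving, so the median of calibrated
    volumes equals the calibrated median of the indices.
    """
    if cfg is None:
        cfg = CalibrationConfig()
    if not math.isfinite(index) or index < 0:
        raise ValueError(f"index must be finite and non-negative, got {index!r}")
    return index * cfg.factor(method)


def change_rate(pre_volume: float, post_volume: float) -> float:
    """Rate of liver volume change in percent: (post − pre) / pre × 100.

    Strictly increasing in ``post_volume``; undefined for ``pre_volume <= 0``.
    """
    if not math.isfinite(pre_volume) or pre_volume <= 0:
        raise ValueError(f"pre_volume must be strictly positive, got {pre_volume!r}")
    if not math.isfinite(post_volume):
        raise ValueError(f"post_volume must be finite, got {post_volume!r}")
    return (post_volume - pre_volume) / pre_volume * 100.0
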