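"""Automated diameter extraction and voxel-count volumetry on 3D liver masks.

A :class:`LiverMask` is a binary voxel grid with mm spacing in a canonical
RAS-like orientation:

* axis 0 — left → right (medial–lateral, ML)
* axis 1 — posterior → anterior (anterior–posterior, AP)
* axis 2 — inferior → superior (cranio-caudal, CC); an axial slice is a
  fixed index on this axis and the slice thickness is ``spacing[2]``.

NIfTI volumes are reoriented to these axes at load time using the header
affine, so every downstream measurement can assume them. Coordinates are
voxel-center based and 0-based; extents are measured between outer voxel
faces, i.e. ``(index span + 1) × spacing``, so a single voxel has extent
equal to the spacing rather than zero.

The voxel-count :func:`reference_volume` stands in for the workstation's
semi-automatic volumetry (slice-wise manual tracing summed to a volume):
the mask *is* the traced region.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np

from .model import DiameterSetBASiM, DiameterSetQDSiM

logger = logging.getLogger(__name__)

__all__ = [
    "LiverMask",
    "LandmarkConfig",
    "MaskError",
    "EmptyMaskError",
    "OrientationError",
    "load_mask",
    "save_mask",
    "reference_volume",
    "basim_diameters",
    "qdsim_diameters",
    "resample_thickness",
]


class MaskError(ValueError):
    """Base class for mask-related errors."""


class EmptyMaskError(MaskError):
    """The mask contains no foreground voxels."""


class OrientationError(MaskError):
    """The image header does not define a usable orientation."""


@dataclass
class LiverMask:
    """Binary liver segmentation on a regular grid.

    Parameters
    ----------
    data : ndarray of bool, shape (nx, ny, nz)
        Foreground marks liver. Axes follow the canonical orientation
        documented in the module docstring.
    spacing : tuple of float
        Voxel spacing (dx, dy, dz) in mm; dz is the axial slice thickness.
    """

    data: np.ndarray
    spacing: tuple

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise MaskError(f"mask must be 3-D, got shape {self.data.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 or not np.isfinite(s) for s in self.spacing):
            raise MaskError(f"spacing must be three positive numbers, got {self.spacing}")

    @property
    def voxel_volume_mm3(self) -> float:
        return self.spacing[0] * self.spacing[1] * self.spacing[2]

    def require_nonempty(self) -> None:
        if not self.data.any():
            raise EmptyMaskError("mask has no foreground voxels")


@dataclass
class LandmarkConfig:
    """Optional anatomical references for diameter measurement.

    posterior_landmark_mm : scalar or per-axial-slice array, optional
        Physical coordinate (mm, along axis 1 with the origin at the
        posterior face of voxel row 0) of the posterior AP reference —
        clinically the junction of the lamina plate and the spinous
        process. When absent, AP falls back to the posterior-most liver
        voxel on the selected slice.
    midline : float, optional
        Left/right split position on axis 0, in voxel-index units (a voxel
        with index ``i`` has its center at ``i + 0.5``). Defaults to the
        grid center, approximating the body's median for a centered scan.
    """

    posterior_landmark_mm: Optional[Union[float, Sequence[float]]] = None
    midline: Optional[float] = None

    def landmark_at(self, z: int, nz: int) -> Optional[float]:
        if self.posterior_landmark_mm is None:
            return None
        lm = self.posterior_landmark_mm
        if np.isscalar(lm):
            return float(lm)
        arr = np.asarray(lm, dtype=float)
        if arr.shape != (nz,):
            raise MaskError(
                f"per-slice landmark must have one value per axial slice ({nz}), got shape {arr.shape}"
            )
        return float(arr[z])


def landmark_from_spine(spine: LiverMask) -> np.ndarray:
    """Per-slice posterior landmark (mm) from a spine segmentation.

    Uses the anterior outer face of the spine mask on each axial slice;
    slices without spine voxels get NaN (callers should restrict to slices
    where the liver is measured).
    """
    spine.require_nonempty()
    nz = spine.data.shape[2]
    out = np.full(nz, np.nan)
    dy = spine.spacing[1]
    for z in range(nz):
        ys = np.nonzero(spine.data[:, :, z].any(axis=0))[0]
        if ys.size:
            out[z] = (ys.max() + 1) * dy
    return out


def load_mask(path, threshold: float = 0.5) -> LiverMask:
    """Read a NIfTI segmentation and reorient it to the canonical axes.

    The header affine is used to bring the array to RAS-like axes
    (left→right, posterior→anterior, inferior→superior); spacing is taken
    from the reoriented affine. Values above ``threshold`` are foreground.
    """
    import nibabel as nib

    img = nib.load(str(path))
    affine = np.asarray(img.affine, dtype=float)
    if not np.all(np.isfinite(affine)) or abs(np.linalg.det(affine[:3, :3])) < 1e-12:
        raise OrientationError(f"{path}: header affine is degenerate or non-finite")
    img = nib.as_closest_canonical(img)
    data = np.asanyarray(img.dataobj)
    spacing = tuple(float(s) for s in np.sqrt((np.asarray(img.affine)[:3, :3] ** 2).sum(axis=0)))
    return LiverMask(data > threshold, spacing)


def save_mask(mask: LiverMask, path) -> None:
    """Write a mask as uint8 NIfTI with a diagonal RAS affine."""
    import nibabel as nib

    affine = np.diag(list(mask.spacing) + [1.0])
    nib.save(nib.Nifti1Image(mask.data.astype(np.uint8), affine), str(path))


def reference_volume(mask: LiverMask) -> float:
    """Voxel-count volume in mL: foreground count × voxel volume / 1000."""
    mask.require_nonempty()
    return int(mask.data.sum()) * mask.voxel_volume_mm3 / 1000.0


def _slice_extent_cm(indices: np.ndarray, spacing: float) -> float:
    return (int(indices.max()) - int(indices.min()) + 1) * spacing / 10.0


def basim_diameters(mask: LiverMask, lm: LandmarkConfig | None = None) -> DiameterSetBASiM:
    """Measure the BASiM diameters CC, AP, ML (cm) from a mask.

    CC counts the axial slices containing liver and multiplies by the
    slice thickness. The measurement slice is the one whose foreground
    attains the global anterior-most coordinate (most cranial slice on
    ties); AP runs from that slice's anterior-most voxel to the posterior
    landmark, falling back to the slice's posterior-most liver voxel, and
    ML is the transverse liver extent on the same slice.
    """
    mask.require_nonempty()
    if lm is None:
        lm = LandmarkConfig()
    dx, dy, dz = mask.spacing
    fg = mask.data
    nz = fg.shape[2]

    slice_has_fg = fg.any(axis=(0, 1))
    cc = int(slice_has_fg.sum()) * dz / 10.0

    # anterior-most coordinate per slice; -1 for empty slices
    per_slice_ant = np.full(nz, -1, dtype=int)
    any_xy = fg.any(axis=0)  # (ny, nz)
    for z in np.nonzero(slice_has_fg)[0]:
        per_slice_ant[z] = int(np.nonzero(any_xy[:, z])[0].max())
    a_global = per_slice_ant.max()
    z_sel = int(np.nonzero(per_slice_ant == a_global)[0].max())  # most cranial tie-break

    sl = fg[:, :, z_sel]
    ys = np.nonzero(sl.any(axis=0))[0]
    xs = np.nonzero(sl.any(axis=1))[0]

    landmark = lm.landmark_at(z_sel, nz)
    if landmark is None:
        ap = _slice_extent_cm(ys, dy)
    else:
        anterior_face_mm = (int(ys.max()) + 1) * dy
        ap = (anterior_face_mm - landmark) / 10.0
        if ap <= 0:
            raise MaskError(
                f"posterior landmark ({landmark} mm) lies at or anterior to the liver's "
                f"ventral surface ({anterior_face_mm} mm) on slice {z_sel}"
            )
    ml = _slice_extent_cm(xs, dx)
    return DiameterSetBASiM(cc=cc, ap=ap, ml=ml, slice_thickness_mm=dz)


def _max_transverse_slice(fg: np.ndarray, dx: float) -> tuple:
    """Axial slice index maximizing the whole-liver left–right extent.

    Returns (slice index, extent in cm); most cranial slice wins ties.
    """
    nz = fg.shape[2]
    any_xz = fg.any(axis=1)  # (nx, nz)
    best_z, best_ext = -1, -1.0
    for z in range(nz):
        xs = np.nonzero(any_xz[:, z])[0]
        if xs.size == 0:
            continue
        ext = _slice_extent_cm(xs, dx)
        if ext >= best_ext:  # >= keeps the most cranial on ties
            best_ext, best_z = ext, z
    return best_z, best_ext


def qdsim_diameters(mask: LiverMask, lm: LandmarkConfig | None = None) -> DiameterSetQDSiM:
    """Measure the QDSiM diameters (cm) from a mask.

    The foreground is split at the midline on axis 0 (body's median;
    defaults to the grid center). Per side: cc = liver-containing slice
    count × thickness; ap = maximum per-slice anterior–posterior extent
    over all slices. ML is the transverse extent on the slice with the
    largest whole-liver transverse diameter. An empty side degrades to
    zero diameters with a warning.
    """
    mask.require_nonempty()
    if lm is None:
        lm = LandmarkConfig()
    dx, dy, dz = mask.spacing
    fg = mask.data
    nx = fg.shape[0]
    midline = lm.midline if lm.midline is not None else nx / 2.0
    if not 0 <= midline <= nx:
        raise MaskError(f"midline {midline} outside grid [0, {nx}]")

    centers = np.arange(nx) + 0.5
    left = fg[centers < midline, :, :]
    right = fg[centers >= midline, :, :]

    def side_cc_ap(side: np.ndarray, name: str) -> tuple:
        if side.size == 0 or not side.any():
            logger.warning("no liver voxels on the %s side of the midline; side diameters set to 0", name)
            return 0.0, 0.0
        zmask = side.any(axis=(0, 1))
        cc = int(zmask.sum()) * dz / 10.0
        any_yz = side.any(axis=0)  # (ny, nz)
        ap = 0.0
        for z in np.nonzero(zmask)[0]:
            ys = np.nonzero(any_yz[:, z])[0]
            ap = max(ap, _slice_extent_cm(ys, dy))
        return cc, ap

    lcc, lap = side_cc_ap(left, "left")
    rcc, rap = side_cc_ap(right, "right")
    _, ml = _max_transverse_slice(fg, dx)
    return DiameterSetQDSiM(lcc=lcc, lap=lap, rcc=rcc, rap=rap, ml=ml, slice_thickness_mm=dz)


def resample_thickness(mask: LiverMask, new_dz: float, interpolate: bool = False) -> LiverMask:
    """Rebin the mask to a new axial slice thickness.

    An output slice covers the interval ``[k·new_dz, (k+1)·new_dz)`` along
    axis 2 (shared origin with the source grid) and is foreground where
    the overlap-weighted foreground fraction of the source column is at
    least 0.5. Going to a *thinner* spacing requires ``interpolate=True``
    since it implies sub-slice information.
    """
    if not np.isfinite(new_dz) or new_dz <= 0:
        raise MaskError(f"new_dz must be positive, got {new_dz!r}")
    dx, dy, dz = mask.spacing
    if new_dz == dz:
        return LiverMask(mask.data.copy(), mask.spacing)
    if new_dz < dz and not interpolate:
        raise MaskError(
            f"resampling {dz} mm → {new_dz} mm slices needs interpolation; pass interpolate=True"
        )
    nz = mask.data.shape[2]
    extent = nz * dz
    n_new = int(np.ceil(extent / new_dz - 1e-9))
    # overlap weights between source slice j (cover [j dz,(j+1) dz)) and new slice k
    w = np.zeros((nz, n_new))
    for k in range(n_new):
        lo, hi = k * new_dz, min((k + 1) * new_dz, extent)
        j0, j1 = int(np.floor(lo / dz)), int(np.ceil(hi / dz - 1e-9))
        for j in range(j0, min(j1, nz)):
            w[j, k] = max(0.0, min((j + 1) * dz, hi) - max(j * dz, lo))
    frac = np.tensordot(mask.data.astype(np.float64), w, axes=([2], [0])) / w.sum(axis=0)
    return LiverMask(frac >= 0.5, (dx, dy, new_dz))
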