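"""Image / mask containers, NIfTI I/O, isotropic resampling and gray-level
discretization.

Volumes are stored as ``(x, y, z)``-indexed numpy arrays with millimetre
spacing, the convention used by nibabel.  Resampling goes through SimpleITK
(trilinear for the image, nearest-neighbor for the mask, so the mask stays
binary).  Discretization maps in-ROI intensities to integer gray levels
``1..Ng`` for the texture-matrix stages; no intensity normalization or outlier
clipping is applied beforehand.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import SimpleITK as sitk


class DegenerateROIError(ValueError):
    """Raised when an operation is asked to work on an empty or unusable ROI."""


class ParameterError(ValueError):
    """Raised for invalid configuration values; the message names the field."""


@dataclass
class ImageVolume:
    voxels: np.ndarray            # 3D float array, (x, y, z) index order
    spacing: tuple[float, float, float]  # mm per voxel along (x, y, z)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float64)
        if self.voxels.ndim != 3 or self.voxels.size == 0:
            raise ParameterError("voxels: expected a non-empty 3D grid")
        if any(s <= 0 for s in self.spacing):
            raise ParameterError("spacing: all components must be > 0")

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))


@dataclass
class ROIMask:
    voxels: np.ndarray            # 3D boolean array aligned to an ImageVolume
    label: str = "supraglottic"

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels).astype(bool)
        if self.voxels.ndim != 3:
            raise ParameterError("mask voxels: expected a 3D grid")
        if not self.voxels.any():
            raise DegenerateROIError("ROI mask has no foreground voxels")

    @property
    def n_voxels(self) -> int:
        return int(self.voxels.sum())


@dataclass
class DiscretizedROI:
    """In-ROI intensities mapped to gray levels 1..Ng; 0 marks background."""

    levels: np.ndarray            # 3D int array, 0 outside the ROI
    Ng: int
    bin_edges: dict               # record of how discretization was done
    n_voxels: int
    voxel_volume: float           # mm^3

    def roi_levels(self) -> np.ndarray:
        return self.levels[self.levels > 0]


# ---------------------------------------------------------------------------
# NIfTI I/O

def read_nifti(path: str | Path) -> ImageVolume:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    zooms = img.header.get_zooms()[:3]
    origin = tuple(float(v) for v in img.affine[:3, 3])
    return ImageVolume(data, tuple(float(z) for z in zooms), origin)


def read_nifti_mask(path: str | Path, label: str = "supraglottic") -> ROIMask:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    return ROIMask(data > 0.5, label=label)


def write_nifti(vol: ImageVolume, path: str | Path) -> None:
    affine = np.diag(list(vol.spacing) + [1.0])
    affine[:3, 3] = vol.origin
    nib.save(nib.Nifti1Image(vol.voxels.astype(np.float32), affine), str(path))


def write_nifti_mask(mask: ROIMask, vol: ImageVolume, path: str | Path) -> None:
    affine = np.diag(list(vol.spacing) + [1.0])
    affine[:3, 3] = vol.origin
    nib.save(nib.Nifti1Image(mask.voxels.astype(np.uint8), affine), str(path))


def check_aligned(img: ImageVolume, mask: ROIMask, *, origin_mask: ImageVolume | None = None,
                  tol_mm: float = 1e-3) -> None:
    """Verify the mask grid matches the image grid (and optionally that two
    volumes share world space to within ``tol_mm``)."""
    if mask.voxels.shape != img.voxels.shape:
        raise ParameterError("mask: grid shape does not match image")
    if origin_mask is not None:
        if (max(abs(a - b) for a, b in zip(img.origin, origin_mask.origin)) > tol_mm
                or max(abs(a - b) for a, b in zip(img.spacing, origin_mask.spacing)) > tol_mm):
            raise ParameterError("mask: world-space alignment exceeds tolerance")


# ---------------------------------------------------------------------------
# Resampling

def _to_sitk(vol: np.ndarray, spacing, origin) -> sitk.Image:
    im = sitk.GetImageFromArray(np.ascontiguousarray(vol.transpose(2, 1, 0)))
    im.SetSpacing(tuple(float(s) for s in spacing))
    im.SetOrigin(tuple(float(o) for o in origin))
    return im


def _from_sitk(im: sitk.Image) -> np.ndarray:
    return sitk.GetArrayFromImage(im).transpose(2, 1, 0)


def resample_isotropic(img: ImageVolume, mask: ROIMask, iso_mm: float = 1.0
                       ) -> tuple[ImageVolume, ROIMask]:
    """Resample image and mask to isotropic ``iso_mm`` spacing.

    The image is interpolated trilinearly, the mask by nearest neighbor.  When
    the input is already isotropic at ``iso_mm`` the grids are returned
    unchanged.
    """
    if iso_mm <= 0:
        raise ParameterError("iso_mm: must be > 0")
    check_aligned(img, mask)
    if all(abs(s - iso_mm) < 1e-9 for s in img.spacing):
        return img, mask

    new_size = [max(1, int(round(n * s / iso_mm)))
                for n, s in zip(img.voxels.shape, img.spacing)]
    ref = sitk.Image(new_size, sitk.sitkFloat64)
    ref.SetSpacing((iso_mm,) * 3)
    ref.SetOrigin(tuple(float(o) for o in img.origin))

    sim = _to_sitk(img.voxels, img.spacing, img.origin)
    sms = _to_sitk(mask.voxels.astype(np.uint8), img.spacing, img.origin)
    out_img = sitk.Resample(sim, ref, sitk.Transform(), sitk.sitkLinear, 0.0)
    out_msk = sitk.Resample(sms, ref, sitk.Transform(), sitk.sitkNearestNeighbor, 0)

    new_mask = _from_sitk(out_msk) > 0.5
    if not new_mask.any():
        raise DegenerateROIError("ROI vanished during isotropic resampling")
    return (ImageVolume(_from_sitk(out_img), (iso_mm,) * 3, img.origin),
            ROIMask(new_mask, label=mask.label))


# ---------------------------------------------------------------------------
# Discretization

def discretize(img: ImageVolume, mask: ROIMask, method: str = "fixed_bin_count",
               param: float = 32) -> DiscretizedROI:
    """Map in-ROI intensities to integer gray levels 1..Ng.

    ``fixed_bin_count``: level = 1 + floor((x - min) * Ng / (max - min + eps)),
    clipped to Ng; a constant ROI maps every voxel to level 1.
    ``fixed_bin_width``: level = 1 + floor((x - min) / w).
    Both are monotone in the intensity.
    """
    check_aligned(img, mask)
    fg = mask.voxels
    x = img.voxels[fg]
    levels = np.zeros(img.voxels.shape, dtype=np.int64)
    mn, mx = float(x.min()), float(x.max())

    if method == "fixed_bin_count":
        ng = int(param)
        if ng < 1 or ng != param:
            raise ParameterError("param: fixed_bin_count requires a positive integer")
        if mx == mn:
            lv = np.ones(x.shape, dtype=np.int64)
            ng_out = ng
        else:
            eps = (mx - mn) * 1e-10
            lv = 1 + np.floor((x - mn) * ng / (mx - mn + eps)).astype(np.int64)
            lv = np.clip(lv, 1, ng)
            ng_out = ng
        record = {"method": method, "Ng": ng, "min": mn, "max": mx}
    elif method == "fixed_bin_width":
        w = float(param)
        if w <= 0:
            raise ParameterError("param: fixed_bin_width requires a positive width")
        lv = 1 + np.floor((x - mn) / w).astype(np.int64)
        ng_out = int(lv.max())
        record = {"method": method, "width": w, "min": mn, "max": mx}
    else:
        raise ParameterError(f"method: unknown discretization method {method!r}")

    levels[fg] = lv
    return DiscretizedROI(levels=levels, Ng=ng_out, bin_edges=record,
                          n_voxels=int(fg.sum()), voxel_volume=img.voxel_volume)
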