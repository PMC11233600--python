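"""The `AnnotatedVolume` container: a 3D intensity grid with an aligned binary ROI mask.

Every image-side stage of the pipeline (clipping, resampling, dilation,
habitat clustering, feature extraction) consumes and produces this unit.
Intensities are Hounsfield units on an axis-aligned grid with per-axis
voxel spacing in millimetres.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["AnnotatedVolume", "load_nifti_pair", "save_nifti_pair"]


@dataclass
class AnnotatedVolume:
    """3D HU volume plus aligned binary region-of-interest mask.

    Parameters
    ----------
    intensities
        3D float array of Hounsfield units.
    spacing_mm
        Per-axis voxel size (dx, dy, dz) in millimetres, strictly positive.
    mask
        Boolean array of the same shape; True marks tumor (ROI) voxels.
    origin_mm
        Physical offset of voxel (0, 0, 0); carried through resampling.
    """

    intensities: np.ndarray
    spacing_mm: tuple[float, float, float]
    mask: np.ndarray
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=np.float64)
        self.mask = np.asarray(self.mask).astype(bool)
        if self.intensities.ndim != 3:
            raise ValueError("intensities must be a 3D array")
        if self.mask.shape != self.intensities.shape:
            raise ValueError(
                f"mask shape {self.mask.shape} does not match "
                f"intensity shape {self.intensities.shape}"
            )
        spacing = tuple(float(s) for s in self.spacing_mm)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError(f"spacing must be three positive values, got {self.spacing_mm}")
        self.spacing_mm = spacing
        self.origin_mm = tuple(float(o) for o in self.origin_mm)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))

    @property
    def n_roi_voxels(self) -> int:
        return int(self.mask.sum())

    def with_(self, **kwargs) -> "AnnotatedVolume":
        """Return a shallow copy with the given fields replaced."""
        return replace(self, **kwargs)


def _affine(spacing: tuple[float, float, float], origin: tuple[float, float, float]) -> np.ndarray:
    aff = np.diag(list(spacing) + [1.0])
    aff[:3, 3] = origin
    return aff


def save_nifti_pair(vol: AnnotatedVolume, image_path: str | Path, mask_path: str | Path) -> None:
    """Write intensity and mask grids as a NIfTI pair sharing one affine."""
    aff = _affine(vol.spacing_mm, vol.origin_mm)
    nib.save(nib.Nifti1Image(vol.intensities.astype(np.float32), aff), str(image_path))
    nib.save(nib.Nifti1Image(vol.mask.astype(np.uint8), aff), str(mask_path))


def load_nifti_pair(image_path: str | Path, mask_path: str | Path) -> AnnotatedVolume:
    """Load an intensity/mask NIfTI pair written by :func:`save_nifti_pair`."""
    img = nib.load(str(image_path))
    msk = nib.load(str(mask_path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(o) for o in img.affine[:3, 3])
    data = np.asanyarray(img.dataobj).astype(np.float64)
    mask = np.asanyarray(msk.dataobj) > 0.5
    if mask.shape != data.shape:
        raise ValueError(f"mask {mask_path} does not align with image {image_path}")
    return AnnotatedVolume(data, spacing, mask, origin)
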