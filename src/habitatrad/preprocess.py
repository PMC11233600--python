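"""Volume standardization: HU clipping and isotropic resampling.

Scanners differ in reconstruction kernel and voxel spacing, so radiomic
features computed on raw volumes are not comparable across centers. Two
standardizations, applied in this fixed order, make them so:

1. clip intensities to [-800, 800] HU to suppress extreme values;
2. resample to an isotropic 1 mm^3 grid (tri-linear for intensities,
   mask interpolated as a float field and re-binarized at 0.5).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import SimpleITK as sitk

from .volume import AnnotatedVolume

__all__ = ["clip_intensities", "resample_isotropic", "preprocess_volume"]

CLIP_LO_HU = -800.0
CLIP_HI_HU = 800.0
TARGET_SPACING_MM = 1.0

_INTERPOLATORS = {"linear": sitk.sitkLinear, "nearest": sitk.sitkNearestNeighbor,
                  "bspline": sitk.sitkBSpline}


def clip_intensities(vol: AnnotatedVolume, lo: float = CLIP_LO_HU, hi: float = CLIP_HI_HU) -> AnnotatedVolume:
    """Clamp every voxel to [lo, hi] HU; mask and geometry unchanged."""
    if not lo < hi:
        raise ValueError(f"need lo < hi, got [{lo}, {hi}]")
    return vol.with_(intensities=np.clip(vol.intensities, lo, hi))


def _to_sitk(arr: np.ndarray, vol: AnnotatedVolume) -> sitk.Image:
    # SimpleITK uses (z, y, x) array order; keep our (x, y, z) convention
    # by transposing on the way in and out.
    img = sitk.GetImageFromArray(np.ascontiguousarray(arr.T))
    img.SetSpacing(tuple(vol.spacing_mm))
    img.SetOrigin(tuple(vol.origin_mm))
    return img


def resample_isotropic(
    vol: AnnotatedVolume,
    target_mm: float = TARGET_SPACING_MM,
    intensity_interpolation: str = "linear",
    sample_name: str | None = None,
) -> AnnotatedVolume:
    """Resample to an isotropic grid of ``target_mm`` voxels.

    Output shape per axis is round(extent / target), which preserves the
    physical extent to within one output voxel. The mask is resampled as
    a float field and re-binarized at 0.5.
    """
    if target_mm <= 0:
        raise ValueError("target spacing must be positive")
    in_shape = np.asarray(vol.shape)
    in_spacing = np.asarray(vol.spacing_mm)
    out_shape = np.maximum(1, np.round(in_shape * in_spacing / target_mm)).astype(int)

    out_spacing = (float(target_mm),) * 3

    def _resample(arr: np.ndarray, interp: str, default: float) -> np.ndarray:
        img = _to_sitk(arr.astype(np.float64), vol)
        res = sitk.Resample(
            img,
            [int(n) for n in out_shape],
            sitk.Transform(),
            _INTERPOLATORS[interp],
            tuple(vol.origin_mm),
            out_spacing,
            (1.0, 0.0, 0.0, 0.0, 1.0, 0.0, 0.0, 0.0, 1.0),
            float(default),
            sitk.sitkFloat64,
        )
        return sitk.GetArrayFromImage(res).T

    new_int = _resample(vol.intensities, intensity_interpolation, float(vol.intensities.min()))
    new_mask = _resample(vol.mask.astype(np.float64), "linear", 0.0) >= 0.5
    if vol.mask.any() and not new_mask.any():
        name = sample_name or vol.meta.get("sample_id", "<unnamed>")
        raise ValueError(f"mask of sample {name} is empty after resampling to {target_mm} mm")
    return AnnotatedVolume(new_int, out_spacing, new_mask, vol.origin_mm, dict(vol.meta))


def preprocess_volume(
    vol: AnnotatedVolume,
    lo: float = CLIP_LO_HU,
    hi: float = CLIP_HI_HU,
    target_mm: float = TARGET_SPACING_MM,
    sidecar_path: str | Path | None = None,
) -> AnnotatedVolume:
    """Clip then resample (fixed order); optionally log parameters to JSON."""
    out = resample_isotropic(clip_intensities(vol, lo, hi), target_mm)
    out.meta["preprocess"] = {"clip_lo_hu": lo, "clip_hi_hu": hi, "target_spacing_mm": target_mm,
                              "order": ["clip", "resample"]}
    if sidecar_path is not None:
        Path(sidecar_path).write_text(json.dumps(out.meta["preprocess"], indent=2))
    return out
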