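"""Image transformations feeding the intensity/texture feature bank.

``transform_bank`` returns the original volume plus Laplacian-of-Gaussian
responses at the configured sigmas (physical mm, anisotropy-aware) and
the 8 sub-bands of a single-level 3D stationary wavelet transform
(undecimated, so every sub-band stays aligned with the ROI mask).
Sub-band tags use L (low-pass) / H (high-pass) per axis, LLL..HHH.
"""

from __future__ import annotations

import warnings

import numpy as np
import pywt
from scipy import ndimage

from ..volume import AnnotatedVolume

__all__ = ["log_transform", "wavelet_transforms", "transform_bank"]

DEFAULT_LOG_SIGMAS_MM = (1.0, 3.0)
DEFAULT_WAVELET = "coif1"


def log_transform(vol: AnnotatedVolume, sigma_mm: float) -> np.ndarray:
    """Laplacian-of-Gaussian response at physical scale ``sigma_mm``.

    The kernel is truncated at 8 sigma so the discrete second-derivative
    weights sum to ~0 and a constant image maps to (numerically) zero.
    """
    sigma_vox = [sigma_mm / s for s in vol.spacing_mm]
    return ndimage.gaussian_laplace(vol.intensities, sigma=sigma_vox, truncate=8.0)


def wavelet_transforms(vol: AnnotatedVolume, wavelet: str = DEFAULT_WAVELET) -> dict[str, np.ndarray]:
    """Single-level stationary 3D wavelet sub-bands, tagged LLL..HHH."""
    data = vol.intensities
    pad = [(0, (-n) % 2) for n in data.shape]  # swt needs even extents
    padded = np.pad(data, pad, mode="symmetric")
    coeffs = pywt.swtn(padded, wavelet, level=1)[0]
    out = {}
    for key, arr in coeffs.items():
        tag = "".join("L" if c == "a" else "H" for c in key)
        out[f"wavelet-{tag}"] = arr[tuple(slice(0, n) for n in data.shape)]
    return out


def transform_bank(
    vol: AnnotatedVolume,
    log_sigmas_mm=DEFAULT_LOG_SIGMAS_MM,
    wavelet: str | None = DEFAULT_WAVELET,
) -> dict[str, np.ndarray]:
    """All transformed intensity grids, keyed by provenance tag.

    A LoG sigma exceeding the ROI physical extent is skipped with a
    warning (the response would be dominated by out-of-region context).
    """
    bank: dict[str, np.ndarray] = {"original": vol.intensities}
    if vol.mask.any():
        idx = np.argwhere(vol.mask)
        extent = ((idx.max(axis=0) - idx.min(axis=0) + 1) * np.asarray(vol.spacing_mm)).max()
    else:
        extent = np.inf
    for sigma in log_sigmas_mm or ():
        if sigma > extent:
            warnings.warn(
                f"LoG sigma {sigma} mm exceeds ROI extent {extent:.1f} mm; transform skipped",
                stacklevel=2,
            )
            continue
        bank[f"log-sigma-{sigma:g}mm"] = log_transform(vol, sigma)
    if wavelet:
        bank.update(wavelet_transforms(vol, wavelet))
    return bank
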