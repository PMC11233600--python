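"""Gray-level discretization for texture and histogram features."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["DiscretizationSpec", "discretize"]


@dataclass(frozen=True)
class DiscretizationSpec:
    """How continuous intensities map to gray levels 1..Ng.

    ``fixed_bin_width`` (default, 25 HU) anchors bins at the ROI minimum:
    g = floor((x - min) / w) + 1. ``fixed_bin_count`` splits [min, max]
    into ``n_bins`` equal bins (a constant region maps to level 1).
    """

    mode: str = "fixed_bin_width"
    bin_width: float = 25.0
    n_bins: int = 32

    def __post_init__(self):
        if self.mode not in ("fixed_bin_width", "fixed_bin_count"):
            raise ValueError(f"unknown discretization mode {self.mode!r}")
        if self.mode == "fixed_bin_width" and self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        if self.mode == "fixed_bin_count" and self.n_bins < 1:
            raise ValueError("n_bins must be >= 1")


def discretize(values: np.ndarray, spec: DiscretizationSpec = DiscretizationSpec()) -> np.ndarray:
    """Map intensities to integer gray levels starting at 1."""
    values = np.asarray(values, dtype=np.float64)
    if values.size == 0:
        raise ValueError("cannot discretize an empty value set")
    lo = values.min()
    if spec.mode == "fixed_bin_width":
        return (np.floor((values - lo) / spec.bin_width) + 1).astype(np.int64)
    hi = values.max()
    if hi == lo:
        return np.ones(values.shape, dtype=np.int64)
    g = np.floor((values - lo) / (hi - lo) * spec.n_bins) + 1
    return np.minimum(g, spec.n_bins).astype(np.int64)
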