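"""First-order intensity statistics of a region (18 features).

Moments are population moments. Conventions for a constant region:
skewness = 0 and kurtosis = 0 (both are 0/0 otherwise), entropy = 0,
uniformity = 1.  Entropy is in bits over the discretized histogram.
Kurtosis is the uncorrected fourth standardized moment (no -3 shift).
"""

from __future__ import annotations

import numpy as np

from .discretize import DiscretizationSpec, discretize

__all__ = ["FIRSTORDER_NAMES", "first_order_features"]

FIRSTORDER_NAMES = (
    "energy",
    "total_energy",
    "entropy",
    "minimum",
    "percentile10",
    "percentile90",
    "maximum",
    "mean",
    "median",
    "interquartile_range",
    "range",
    "mean_absolute_deviation",
    "robust_mean_absolute_deviation",
    "root_mean_squared",
    "skewness",
    "kurtosis",
    "variance",
    "uniformity",
)


def first_order_features(
    values: np.ndarray,
    voxel_volume_mm3: float = 1.0,
    disc: DiscretizationSpec = DiscretizationSpec(),
) -> dict[str, float]:
    """First-order features of the ROI intensity sample ``values``."""
    x = np.asarray(values, dtype=np.float64).ravel()
    if x.size == 0:
        raise ValueError("region is empty")
    n = x.size
    mean = x.mean()
    var = x.var()  # population
    sd = np.sqrt(var)
    p10, p25, p75, p90 = np.percentile(x, [10, 25, 75, 90])
    centered = x - mean
    if sd > 0:
        skew = float(np.mean(centered**3) / sd**3)
        kurt = float(np.mean(centered**4) / var**2)
    else:
        skew = 0.0
        kurt = 0.0
    robust = x[(x >= p10) & (x <= p90)]
    rmad = float(np.abs(robust - robust.mean()).mean()) if robust.size else 0.0

    g = discretize(x, disc)
    counts = np.bincount(g)[1:]
    p = counts[counts > 0] / n
    entropy = float(-np.sum(p * np.log2(p)))
    uniformity = float(np.sum(p * p))

    energy = float(np.sum(x * x))
    return {
        "energy": energy,
        "total_energy": energy * float(voxel_volume_mm3),
        "entropy": entropy,
        "minimum": float(x.min()),
        "percentile10": float(p10),
        "percentile90": float(p90),
        "maximum": float(x.max()),
        "mean": float(mean),
        "median": float(np.median(x)),
        "interquartile_range": float(p75 - p25),
        "range": float(x.max() - x.min()),
        "mean_absolute_deviation": float(np.abs(centered).mean()),
        "robust_mean_absolute_deviation": rmad,
        "root_mean_squared": float(np.sqrt(np.mean(x * x))),
        "skewness": skew,
        "kurtosis": kurt,
        "variance": float(var),
        "uniformity": uniformity,
    }
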