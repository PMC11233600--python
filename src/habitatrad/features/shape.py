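"""Shape descriptors of a binary mask (14 features, intensity-independent).

Mesh quantities come from a marching-cubes surface of the 0.5 level set
(mask padded by one voxel so the surface is closed). Axis lengths are
4 * sqrt(eigenvalue) of the physical-coordinate covariance (population
moments). Degenerate masks (single voxel, coplanar voxels) yield the
documented conventions below rather than NaN, with a warning.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import pdist
from skimage import measure

__all__ = ["SHAPE_NAMES", "shape_features"]

SHAPE_NAMES = (
    "mesh_volume",
    "voxel_volume",
    "surface_area",
    "surface_volume_ratio",
    "sphericity",
    "max_3d_diameter",
    "max_2d_diameter_slice",
    "max_2d_diameter_row",
    "max_2d_diameter_column",
    "major_axis_length",
    "minor_axis_length",
    "least_axis_length",
    "elongation",
    "flatness",
)


def _mesh(mask: np.ndarray, spacing) -> tuple[float, float]:
    padded = np.pad(mask.astype(np.float64), 1)
    verts, faces, _, _ = measure.marching_cubes(padded, level=0.5, spacing=tuple(spacing))
    area = float(measure.mesh_surface_area(verts, faces))
    tri = verts[faces]
    vol = float(abs(np.einsum("ij,ij->i", tri[:, 0], np.cross(tri[:, 1], tri[:, 2])).sum()) / 6.0)
    return vol, area


def _max_pairwise(points: np.ndarray) -> float:
    if len(points) < 2:
        return 0.0
    if len(points) > 400:
        try:
            points = points[ConvexHull(points).vertices]
        except QhullError:
            pass  # degenerate (flat) point sets: fall through to brute force
    return float(pdist(points).max())


def shape_features(mask: np.ndarray, spacing_mm) -> dict[str, float]:
    """The 14 shape descriptors of a nonempty binary mask."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    spacing = np.asarray(spacing_mm, dtype=np.float64)
    nvox = int(mask.sum())
    coords = np.argwhere(mask) * spacing

    mesh_volume, surface_area = _mesh(mask, spacing)
    voxel_volume = nvox * float(np.prod(spacing))
    sphericity = (36.0 * np.pi * mesh_volume**2) ** (1.0 / 3.0) / surface_area

    if nvox < 2:
        warnings.warn("single-voxel mask: axis and diameter descriptors are degenerate",
                      stacklevel=2)
        lengths = np.zeros(3)
        elong = flat = 0.0
        d3 = d_sl = d_row = d_col = 0.0
    else:
        cov = np.cov(coords.T, ddof=0)
        eig = np.sort(np.linalg.eigvalsh(cov))[::-1]
        eig = np.clip(eig, 0.0, None)
        lengths = 4.0 * np.sqrt(eig)
        if eig[0] > 0:
            elong = float(np.sqrt(eig[1] / eig[0]))
            flat = float(np.sqrt(eig[2] / eig[0]))
        else:
            warnings.warn("zero-extent mask: elongation/flatness set to 0", stacklevel=2)
            elong = flat = 0.0
        idx = np.argwhere(mask)
        d3 = _max_pairwise(idx * spacing)
        phys = idx * spacing
        d_sl = _max_2d_phys(idx, phys, slice_axis=2)
        d_row = _max_2d_phys(idx, phys, slice_axis=1)
        d_col = _max_2d_phys(idx, phys, slice_axis=0)

    return {
        "mesh_volume": mesh_volume,
        "voxel_volume": voxel_volume,
        "surface_area": surface_area,
        "surface_volume_ratio": surface_area / mesh_volume if mesh_volume > 0 else 0.0,
        "sphericity": sphericity,
        "max_3d_diameter": d3,
        "max_2d_diameter_slice": d_sl,
        "max_2d_diameter_row": d_row,
        "max_2d_diameter_column": d_col,
        "major_axis_length": float(lengths[0]),
        "minor_axis_length": float(lengths[1]),
        "least_axis_length": float(lengths[2]),
        "elongation": elong,
        "flatness": flat,
    }


def _max_2d_phys(idx: np.ndarray, phys: np.ndarray, slice_axis: int) -> float:
    plane = [a for a in range(3) if a != slice_axis]
    best = 0.0
    for s in np.unique(idx[:, slice_axis]):
        pts = phys[idx[:, slice_axis] == s][:, plane]
        best = max(best, _max_pairwise(pts))
    return best
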