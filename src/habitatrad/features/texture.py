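"""The five texture families over a discretized 3D region.

All matrices operate on an integer gray-level grid ``g`` (0 outside the
ROI, 1..Ng inside). Directional matrices (GLCM, GLRLM) use the 13 unique
3D directions of the 26-neighborhood and average per-direction feature
values; GLSZM zones and GLDM dependences use full 26-connectivity;
NGTDM neighborhoods are the in-ROI 26-neighbors.

Degenerate conventions (documented, asserted in tests):

* single gray level: GLCM correlation = 1, MCC = 1, NGTDM contrast /
  busyness / strength = 0, NGTDM coarseness capped at 1e6;
* a voxel with no in-ROI neighbor is excluded from the NGTDM;
* a direction with no co-occurring pair contributes nothing to the GLCM
  average (an isolated single voxel falls back to the 1x1 identity
  matrix).
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .discretize import DiscretizationSpec, discretize

__all__ = [
    "DIRECTIONS_13",
    "OFFSETS_26",
    "TEXTURE_FAMILY_SIZES",
    "glcm_matrix",
    "glcm_features_from_matrix",
    "glrlm_matrix",
    "glrlm_features_from_matrix",
    "glszm_matrix",
    "glszm_features_from_matrix",
    "gldm_matrix",
    "gldm_features_from_matrix",
    "ngtdm_matrix",
    "ngtdm_features_from_matrix",
    "texture_features",
]

#: 13 unique direction vectors (first nonzero component positive).
DIRECTIONS_13 = tuple(
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) > (0, 0, 0)
)

#: All 26 neighbor offsets.
OFFSETS_26 = tuple(
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
)

TEXTURE_FAMILY_SIZES = {"glcm": 24, "glrlm": 16, "glszm": 16, "gldm": 14, "ngtdm": 5}

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


def _shift(a: np.ndarray, off: tuple[int, int, int], fill=0) -> np.ndarray:
    """out[v] = a[v + off], `fill` where v + off falls off-grid."""
    out = np.full_like(a, fill)
    src = []
    dst = []
    for n, d in zip(a.shape, off):
        src.append(slice(d, None) if d >= 0 else slice(None, d))
        dst.append(slice(None, n - d) if d >= 0 else slice(-d, None))
    out[tuple(dst)] = a[tuple(src)]
    return out


def _label_grid(intensities: np.ndarray, mask: np.ndarray, disc: DiscretizationSpec) -> np.ndarray:
    g = np.zeros(mask.shape, dtype=np.int64)
    g[mask] = discretize(intensities[mask], disc)
    return g


# ---------------------------------------------------------------- GLCM

def glcm_matrix(g: np.ndarray, direction: tuple[int, int, int]) -> np.ndarray:
    """Symmetric co-occurrence count matrix for one direction."""
    ng = int(g.max())
    P = np.zeros((ng, ng), dtype=np.float64)
    nb = _shift(g, direction)
    valid = (g > 0) & (nb > 0)
    np.add.at(P, (g[valid] - 1, nb[valid] - 1), 1.0)
    return P + P.T


def _entropy2(p: np.ndarray) -> float:
    pos = p[p > 0]
    return float(-np.sum(pos * np.log2(pos)))


def glcm_features_from_matrix(P: np.ndarray) -> dict[str, float]:
    ng = P.shape[0]
    p = P / P.sum()
    i = np.arange(1, ng + 1, dtype=np.float64)
    I, J = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    ux = float(np.sum(i * px))
    uy = float(np.sum(i * py))
    sx = float(np.sqrt(np.sum((i - ux) ** 2 * px)))
    sy = float(np.sqrt(np.sum((i - uy) ** 2 * py)))

    k_sum = np.arange(2, 2 * ng + 1, dtype=np.float64)
    p_sum = np.array([p[(I + J) == k].sum() for k in k_sum])
    k_diff = np.arange(0, ng, dtype=np.float64)
    p_diff = np.array([p[np.abs(I - J) == k].sum() for k in k_diff])

    diff_avg = float(np.sum(k_diff * p_diff))
    hxy = _entropy2(p)
    hx = _entropy2(px)
    hy = _entropy2(py)
    pxpy = np.outer(px, py)
    pos = pxpy > 0
    hxy1 = float(-np.sum(p[pos] * np.log2(pxpy[pos])))
    hxy2 = float(-np.sum(pxpy[pos] * np.log2(pxpy[pos])))

    corr = 1.0 if sx * sy == 0 else float((np.sum(I * J * p) - ux * uy) / (sx * sy))
    imc1 = 0.0 if max(hx, hy) == 0 else float((hxy - hxy1) / max(hx, hy))
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))

    off = I != J
    inv_var = float(np.sum(p[off] / (I[off] - J[off]) ** 2)) if off.any() else 0.0

    present = px > 0
    if present.sum() < 2:
        mcc = 1.0
    else:
        pp = p[np.ix_(present, present)]
        pxp = px[present]
        pyp = py[present]
        A = pp / pxp[:, None]
        B = pp / pyp[None, :]
        Q = A @ B.T
        ev = np.linalg.eigvals(Q)
        ev = np.sort(np.real(ev))[::-1]
        mcc = float(np.sqrt(max(0.0, ev[1])))

    return {
        "autocorrelation": float(np.sum(I * J * p)),
        "joint_average": ux,
        "cluster_prominence": float(np.sum((I + J - ux - uy) ** 4 * p)),
        "cluster_shade": float(np.sum((I + J - ux - uy) ** 3 * p)),
        "cluster_tendency": float(np.sum((I + J - ux - uy) ** 2 * p)),
        "contrast": float(np.sum((I - J) ** 2 * p)),
        "correlation": corr,
        "difference_average": diff_avg,
        "difference_entropy": _entropy2(p_diff),
        "difference_variance": float(np.sum((k_diff - diff_avg) ** 2 * p_diff)),
        "joint_energy": float(np.sum(p * p)),
        "joint_entropy": hxy,
        "imc1": imc1,
        "imc2": imc2,
        "idm": float(np.sum(p / (1.0 + (I - J) ** 2))),
        "idmn": float(np.sum(p / (1.0 + (I - J) ** 2 / ng**2))),
        "id": float(np.sum(p / (1.0 + np.abs(I - J)))),
        "idn": float(np.sum(p / (1.0 + np.abs(I - J) / ng))),
        "inverse_variance": inv_var,
        "maximum_probability": float(p.max()),
        "sum_average": float(np.sum(k_sum * p_sum)),
        "sum_entropy": _entropy2(p_sum),
        "sum_squares": float(np.sum((I - ux) ** 2 * p)),
        "mcc": mcc,
    }


def _glcm_features(g: np.ndarray) -> dict[str, float]:
    per_dir = []
    for d in DIRECTIONS_13:
        P = glcm_matrix(g, d)
        if P.sum() > 0:
            per_dir.append(glcm_features_from_matrix(P))
    if not per_dir:  # isolated voxel(s): no co-occurring pair anywhere
        per_dir = [glcm_features_from_matrix(np.array([[1.0]]))]
    return {k: float(np.mean([f[k] for f in per_dir])) for k in per_dir[0]}


# --------------------------------------------------------------- GLRLM

def glrlm_matrix(g: np.ndarray, direction: tuple[int, int, int]) -> np.ndarray:
    """Run-length count matrix (gray level x run length) for one direction."""
    ng = int(g.max())
    in_roi = g > 0
    nxt = _shift(g, direction)
    cont = in_roi & (nxt == g) & (nxt > 0)

    L = in_roi.astype(np.int64)
    max_steps = int(sum(abs(d) * (n - 1) for d, n in zip(direction, g.shape))) + 1
    for _ in range(max_steps):
        newL = np.where(cont, 1 + _shift(L, direction), in_roi.astype(np.int64))
        if np.array_equal(newL, L):
            break
        L = newL

    prev = _shift(g, tuple(-d for d in direction))
    start = in_roi & ~((prev == g) & (prev > 0))
    lengths = L[start]
    levels = g[start]
    P = np.zeros((ng, int(lengths.max())), dtype=np.float64)
    np.add.at(P, (levels - 1, lengths - 1), 1.0)
    return P


def glrlm_features_from_matrix(P: np.ndarray, n_voxels: int) -> dict[str, float]:
    nr = P.sum()
    p = P / nr
    i = np.arange(1, P.shape[0] + 1, dtype=np.float64)
    l = np.arange(1, P.shape[1] + 1, dtype=np.float64)
    I, Lg = np.meshgrid(i, l, indexing="ij")
    mu_i = float(np.sum(I * p))
    mu_l = float(np.sum(Lg * p))
    return {
        "short_run_emphasis": float(np.sum(P / Lg**2) / nr),
        "long_run_emphasis": float(np.sum(P * Lg**2) / nr),
        "gray_level_nonuniformity": float(np.sum(P.sum(axis=1) ** 2) / nr),
        "gray_level_nonuniformity_normalized": float(np.sum(P.sum(axis=1) ** 2) / nr**2),
        "run_length_nonuniformity": float(np.sum(P.sum(axis=0) ** 2) / nr),
        "run_length_nonuniformity_normalized": float(np.sum(P.sum(axis=0) ** 2) / nr**2),
        "run_percentage": float(nr / n_voxels),
        "gray_level_variance": float(np.sum(p * (I - mu_i) ** 2)),
        "run_variance": float(np.sum(p * (Lg - mu_l) ** 2)),
        "run_entropy": _entropy2(p.ravel()),
        "low_gray_level_run_emphasis": float(np.sum(P / I**2) / nr),
        "high_gray_level_run_emphasis": float(np.sum(P * I**2) / nr),
        "short_run_low_gray_level_emphasis": float(np.sum(P / (I**2 * Lg**2)) / nr),
        "short_run_high_gray_level_emphasis": float(np.sum(P * I**2 / Lg**2) / nr),
        "long_run_low_gray_level_emphasis": float(np.sum(P * Lg**2 / I**2) / nr),
        "long_run_high_gray_level_emphasis": float(np.sum(P * I**2 * Lg**2) / nr),
    }


def _glrlm_features(g: np.ndarray) -> dict[str, float]:
    n_vox = int((g > 0).sum())
    per_dir = [glrlm_features_from_matrix(glrlm_matrix(g, d), n_vox) for d in DIRECTIONS_13]
    return {k: float(np.mean([f[k] for f in per_dir])) for k in per_dir[0]}


# --------------------------------------------------------------- GLSZM

def glszm_matrix(g: np.ndarray) -> np.ndarray:
    """Size-zone count matrix: 26-connected zones of constant gray level."""
    ng = int(g.max())
    pairs: list[tuple[int, int]] = []
    for lvl in range(1, ng + 1):
        lab, nz = ndimage.label(g == lvl, structure=_STRUCT26)
        if nz:
            sizes = np.bincount(lab.ravel())[1:]
            pairs.extend((lvl, int(s)) for s in sizes)
    smax = max(s for _, s in pairs)
    P = np.zeros((ng, smax), dtype=np.float64)
    for lvl, s in pairs:
        P[lvl - 1, s - 1] += 1.0
    return P


def glszm_features_from_matrix(P: np.ndarray, n_voxels: int) -> dict[str, float]:
    nz = P.sum()
    p = P / nz
    i = np.arange(1, P.shape[0] + 1, dtype=np.float64)
    s = np.arange(1, P.shape[1] + 1, dtype=np.float64)
    I, S = np.meshgrid(i, s, indexing="ij")
    mu_i = float(np.sum(I * p))
    mu_s = float(np.sum(S * p))
    return {
        "small_area_emphasis": float(np.sum(P / S**2) / nz),
        "large_area_emphasis": float(np.sum(P * S**2) / nz),
        "gray_level_nonuniformity": float(np.sum(P.sum(axis=1) ** 2) / nz),
        "gray_level_nonuniformity_normalized": float(np.sum(P.sum(axis=1) ** 2) / nz**2),
        "size_zone_nonuniformity": float(np.sum(P.sum(axis=0) ** 2) / nz),
        "size_zone_nonuniformity_normalized": float(np.sum(P.sum(axis=0) ** 2) / nz**2),
        "zone_percentage": float(nz / n_voxels),
        "gray_level_variance": float(np.sum(p * (I - mu_i) ** 2)),
        "zone_variance": float(np.sum(p * (S - mu_s) ** 2)),
        "zone_entropy": _entropy2(p.ravel()),
        "low_gray_level_zone_emphasis": float(np.sum(P / I**2) / nz),
        "high_gray_level_zone_emphasis": float(np.sum(P * I**2) / nz),
        "small_area_low_gray_level_emphasis": float(np.sum(P / (I**2 * S**2)) / nz),
        "small_area_high_gray_level_emphasis": float(np.sum(P * I**2 / S**2) / nz),
        "large_area_low_gray_level_emphasis": float(np.sum(P * S**2 / I**2) / nz),
        "large_area_high_gray_level_emphasis": float(np.sum(P * I**2 * S**2) / nz),
    }


# ---------------------------------------------------------------- GLDM

def gldm_matrix(g: np.ndarray, alpha: float = 0.0) -> np.ndarray:
    """Dependence count matrix: gray level x dependence size (1 + #dependent 26-neighbors)."""
    ng = int(g.max())
    in_roi = g > 0
    dep = np.zeros(g.shape, dtype=np.int64)
    for off in OFFSETS_26:
        nb = _shift(g, off)
        dep += (in_roi & (nb > 0) & (np.abs(nb - g) <= alpha)).astype(np.int64)
    j = dep[in_roi] + 1  # dependence size includes the center voxel
    P = np.zeros((ng, int(j.max())), dtype=np.float64)
    np.add.at(P, (g[in_roi] - 1, j - 1), 1.0)
    return P


def gldm_features_from_matrix(P: np.ndarray) -> dict[str, float]:
    nz = P.sum()
    p = P / nz
    i = np.arange(1, P.shape[0] + 1, dtype=np.float64)
    jj = np.arange(1, P.shape[1] + 1, dtype=np.float64)
    I, J = np.meshgrid(i, jj, indexing="ij")
    mu_i = float(np.sum(I * p))
    mu_j = float(np.sum(J * p))
    return {
        "small_dependence_emphasis": float(np.sum(P / J**2) / nz),
        "large_dependence_emphasis": float(np.sum(P * J**2) / nz),
        "gray_level_nonuniformity": float(np.sum(P.sum(axis=1) ** 2) / nz),
        "dependence_nonuniformity": float(np.sum(P.sum(axis=0) ** 2) / nz),
        "dependence_nonuniformity_normalized": float(np.sum(P.sum(axis=0) ** 2) / nz**2),
        "gray_level_variance": float(np.sum(p * (I - mu_i) ** 2)),
        "dependence_variance": float(np.sum(p * (J - mu_j) ** 2)),
        "dependence_entropy": _entropy2(p.ravel()),
        "low_gray_level_emphasis": float(np.sum(P / I**2) / nz),
        "high_gray_level_emphasis": float(np.sum(P * I**2) / nz),
        "small_dependence_low_gray_level_emphasis": float(np.sum(P / (I**2 * J**2)) / nz),
        "small_dependence_high_gray_level_emphasis": float(np.sum(P * I**2 / J**2) / nz),
        "large_dependence_low_gray_level_emphasis": float(np.sum(P * J**2 / I**2) / nz),
        "large_dependence_high_gray_level_emphasis": float(np.sum(P * I**2 * J**2) / nz),
    }


# --------------------------------------------------------------- NGTDM

def ngtdm_matrix(g: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-level (n_i, s_i): counts and summed |level - neighborhood mean|.

    Voxels with no in-ROI 26-neighbor are excluded.
    """
    ng = int(g.max())
    in_roi = g > 0
    nb_sum = np.zeros(g.shape, dtype=np.float64)
    nb_cnt = np.zeros(g.shape, dtype=np.int64)
    for off in OFFSETS_26:
        nb = _shift(g, off)
        ok = in_roi & (nb > 0)
        nb_sum[ok] += nb[ok]
        nb_cnt[ok] += 1
    has = in_roi & (nb_cnt > 0)
    n = np.zeros(ng, dtype=np.float64)
    s = np.zeros(ng, dtype=np.float64)
    lv = g[has]
    diff = np.abs(lv - nb_sum[has] / nb_cnt[has])
    np.add.at(n, lv - 1, 1.0)
    np.add.at(s, lv - 1, diff)
    return n, s


NGTDM_COARSENESS_CAP = 1e6


def ngtdm_features_from_matrix(n: np.ndarray, s: np.ndarray) -> dict[str, float]:
    N = n.sum()
    if N == 0:  # no voxel has an in-ROI neighbor
        return {"coarseness": NGTDM_COARSENESS_CAP, "contrast": 0.0,
                "busyness": 0.0, "complexity": 0.0, "strength": 0.0}
    p = n / N
    i = np.arange(1, len(n) + 1, dtype=np.float64)
    present = p > 0
    ngp = int(present.sum())
    ip = i[present]
    pp = p[present]
    sp = s[present]

    denom = float(np.sum(p * s))
    coarseness = NGTDM_COARSENESS_CAP if denom == 0 else min(1.0 / denom, NGTDM_COARSENESS_CAP)

    if ngp > 1:
        dd = (ip[:, None] - ip[None, :]) ** 2
        contrast = float(np.sum(pp[:, None] * pp[None, :] * dd) / (ngp * (ngp - 1)) * s.sum() / N)
        bdenom = float(np.sum(np.abs(ip[:, None] * pp[:, None] - ip[None, :] * pp[None, :])))
        busyness = 0.0 if bdenom == 0 else denom / bdenom
        complexity = float(
            np.sum(
                np.abs(ip[:, None] - ip[None, :])
                * (pp[:, None] * sp[:, None] + pp[None, :] * sp[None, :])
                / (pp[:, None] + pp[None, :])
            )
            / N
        )
        ssum = s.sum()
        strength = 0.0 if ssum == 0 else float(
            np.sum((pp[:, None] + pp[None, :]) * dd) / ssum
        )
    else:
        contrast = busyness = complexity = strength = 0.0

    return {"coarseness": coarseness, "contrast": contrast, "busyness": busyness,
            "complexity": complexity, "strength": strength}


# ----------------------------------------------------------- top level

def _crop(intensities: np.ndarray, mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    sl = ndimage.find_objects(mask.astype(np.int8), max_label=1)[0]
    return intensities[sl], mask[sl]


def texture_features(
    intensities: np.ndarray,
    mask: np.ndarray,
    disc: DiscretizationSpec = DiscretizationSpec(),
) -> dict[str, dict[str, float]]:
    """All 75 texture features of a region, grouped by family."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("region is empty")
    intens, m = _crop(np.asarray(intensities, dtype=np.float64), mask)
    g = _label_grid(intens, m, disc)
    n_vox = int(m.sum())
    return {
        "glcm": _glcm_features(g),
        "glrlm": _glrlm_features(g),
        "glszm": glszm_features_from_matrix(glszm_matrix(g), n_vox),
        "gldm": gldm_features_from_matrix(gldm_matrix(g)),
        "ngtdm": ngtdm_features_from_matrix(*ngtdm_matrix(g)),
    }
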