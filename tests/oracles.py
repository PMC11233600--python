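"""Independent brute-force oracles used by the test suite.

Everything here is written as literal formula evaluation — python loops
over voxels, voxel pairs, runs, zones and matrix cells — deliberately
avoiding the vectorized code paths of the package it checks.
"""

from __future__ import annotations

import math
from collections import defaultdict

import numpy as np

NEIGHBORS_26 = [
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
]
DIRECTIONS_13 = [d for d in NEIGHBORS_26 if d > (0, 0, 0)]


def brute_dilate(mask: np.ndarray, spacing, radius: float) -> np.ndarray:
    """O(N*M) distance enumeration of the physical-ball dilation."""
    src = np.argwhere(mask)
    out = np.zeros_like(mask, dtype=bool)
    sp = np.asarray(spacing, float)
    for idx in np.ndindex(mask.shape):
        for s in src:
            d = np.sqrt((((np.asarray(idx) - s) * sp) ** 2).sum())
            if d <= radius:
                out[idx] = True
                break
    return out


def brute_auc(scores, labels) -> float:
    """All-pairs concordance counting, ties worth 1/2."""
    s = np.asarray(scores, float)
    y = np.asarray(labels).astype(int)
    pos = s[y == 1]
    neg = s[y == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                total += 1.0
            elif p == n:
                total += 0.5
    return total / (len(pos) * len(neg))


def discretize_fbw(values, width=25.0):
    lo = min(values)
    return [int(math.floor((v - lo) / width)) + 1 for v in values]


# ------------------------------------------------------- texture oracles

def _in(shape, v):
    return all(0 <= v[a] < shape[a] for a in range(3))


def oracle_glcm_matrix(g: np.ndarray, direction) -> np.ndarray:
    ng = int(g.max())
    P = np.zeros((ng, ng))
    for idx in np.argwhere(g > 0):
        nb = tuple(idx + direction)
        if _in(g.shape, nb) and g[nb] > 0:
            P[g[tuple(idx)] - 1, g[nb] - 1] += 1
            P[g[nb] - 1, g[tuple(idx)] - 1] += 1
    return P


def oracle_glcm_features(P: np.ndarray) -> dict[str, float]:
    ng = P.shape[0]
    tot = P.sum()
    p = P / tot
    px = [sum(p[i][j] for j in range(ng)) for i in range(ng)]
    py = [sum(p[i][j] for i in range(ng)) for j in range(ng)]
    ux = sum((i + 1) * px[i] for i in range(ng))
    uy = sum((j + 1) * py[j] for j in range(ng))
    sx = math.sqrt(sum((i + 1 - ux) ** 2 * px[i] for i in range(ng)))
    sy = math.sqrt(sum((j + 1 - uy) ** 2 * py[j] for j in range(ng)))
    psum = defaultdict(float)
    pdiff = defaultdict(float)
    for i in range(ng):
        for j in range(ng):
            psum[i + j + 2] += p[i][j]
            pdiff[abs(i - j)] += p[i][j]
    da = sum(k * v for k, v in pdiff.items())
    hxy = -sum(v * math.log2(v) for row in p for v in row if v > 0)
    hx = -sum(v * math.log2(v) for v in px if v > 0)
    hy = -sum(v * math.log2(v) for v in py if v > 0)
    hxy1 = -sum(
        p[i][j] * math.log2(px[i] * py[j])
        for i in range(ng)
        for j in range(ng)
        if px[i] * py[j] > 0 and p[i][j] > 0
    )
    hxy2 = -sum(
        px[i] * py[j] * math.log2(px[i] * py[j])
        for i in range(ng)
        for j in range(ng)
        if px[i] * py[j] > 0
    )
    f = {}
    f["autocorrelation"] = sum((i + 1) * (j + 1) * p[i][j] for i in range(ng) for j in range(ng))
    f["joint_average"] = ux
    for name, power in (("cluster_prominence", 4), ("cluster_shade", 3), ("cluster_tendency", 2)):
        f[name] = sum(
            (i + 1 + j + 1 - ux - uy) ** power * p[i][j] for i in range(ng) for j in range(ng)
        )
    f["contrast"] = sum((i - j) ** 2 * p[i][j] for i in range(ng) for j in range(ng))
    if sx * sy == 0:
        f["correlation"] = 1.0
    else:
        f["correlation"] = (f["autocorrelation"] - ux * uy) / (sx * sy)
    f["difference_average"] = da
    f["difference_entropy"] = -sum(v * math.log2(v) for v in pdiff.values() if v > 0)
    f["difference_variance"] = sum((k - da) ** 2 * v for k, v in pdiff.items())
    f["joint_energy"] = sum(v * v for row in p for v in row)
    f["joint_entropy"] = hxy
    f["imc1"] = 0.0 if max(hx, hy) == 0 else (hxy - hxy1) / max(hx, hy)
    f["imc2"] = math.sqrt(max(0.0, 1.0 - math.exp(-2.0 * (hxy2 - hxy))))
    f["idm"] = sum(p[i][j] / (1 + (i - j) ** 2) for i in range(ng) for j in range(ng))
    f["idmn"] = sum(p[i][j] / (1 + (i - j) ** 2 / ng**2) for i in range(ng) for j in range(ng))
    f["id"] = sum(p[i][j] / (1 + abs(i - j)) for i in range(ng) for j in range(ng))
    f["idn"] = sum(p[i][j] / (1 + abs(i - j) / ng) for i in range(ng) for j in range(ng))
    f["inverse_variance"] = sum(
        p[i][j] / (i - j) ** 2 for i in range(ng) for j in range(ng) if i != j
    )
    f["maximum_probability"] = max(v for row in p for v in row)
    f["sum_average"] = sum(k * v for k, v in psum.items())
    f["sum_entropy"] = -sum(v * math.log2(v) for v in psum.values() if v > 0)
    f["sum_squares"] = sum((i + 1 - ux) ** 2 * p[i][j] for i in range(ng) for j in range(ng))
    present = [i for i in range(ng) if px[i] > 0]
    if len(present) < 2:
        f["mcc"] = 1.0
    else:
        Q = np.zeros((len(present), len(present)))
        for a, i in enumerate(present):
            for b, j in enumerate(present):
                Q[a, b] = sum(
                    p[i][k] * p[j][k] / (px[i] * py[k]) for k in range(ng) if py[k] > 0
                )
        ev = sorted(np.real(np.linalg.eigvals(Q)), reverse=True)
        f["mcc"] = math.sqrt(max(0.0, ev[1]))
    return f


def oracle_glrlm_matrix(g: np.ndarray, direction) -> np.ndarray:
    ng = int(g.max())
    runs = []
    for idx in np.argwhere(g > 0):
        prev = tuple(idx - direction)
        if _in(g.shape, prev) and g[prev] == g[tuple(idx)]:
            continue  # not a run start
        length = 1
        cur = idx
        while True:
            nxt = tuple(cur + direction)
            if _in(g.shape, nxt) and g[nxt] == g[tuple(idx)] and g[nxt] > 0:
                length += 1
                cur = np.asarray(nxt)
            else:
                break
        runs.append((g[tuple(idx)], length))
    lmax = max(l for _, l in runs)
    P = np.zeros((ng, lmax))
    for lvl, l in runs:
        P[lvl - 1, l - 1] += 1
    return P


def _weighted_matrix_features(P, n_voxels, row_name, col_name, prefix_map):
    """Shared literal loop formulas for GLRLM/GLSZM-style matrices."""
    ng, lmax = P.shape
    tot = P.sum()
    f = {}
    f[prefix_map["short"]] = sum(
        P[i][l] / (l + 1) ** 2 for i in range(ng) for l in range(lmax)
    ) / tot
    f[prefix_map["long"]] = sum(
        P[i][l] * (l + 1) ** 2 for i in range(ng) for l in range(lmax)
    ) / tot
    f[prefix_map["gln"]] = sum(sum(P[i]) ** 2 for i in range(ng)) / tot
    f[prefix_map["glnn"]] = sum(sum(P[i]) ** 2 for i in range(ng)) / tot**2
    f[prefix_map["rln"]] = sum(sum(P[i][l] for i in range(ng)) ** 2 for l in range(lmax)) / tot
    f[prefix_map["rlnn"]] = (
        sum(sum(P[i][l] for i in range(ng)) ** 2 for l in range(lmax)) / tot**2
    )
    f[prefix_map["pct"]] = tot / n_voxels
    mu_i = sum((i + 1) * P[i][l] / tot for i in range(ng) for l in range(lmax))
    mu_l = sum((l + 1) * P[i][l] / tot for i in range(ng) for l in range(lmax))
    f[prefix_map["glv"]] = sum(
        (i + 1 - mu_i) ** 2 * P[i][l] / tot for i in range(ng) for l in range(lmax)
    )
    f[prefix_map["lv"]] = sum(
        (l + 1 - mu_l) ** 2 * P[i][l] / tot for i in range(ng) for l in range(lmax)
    )
    f[prefix_map["entropy"]] = -sum(
        P[i][l] / tot * math.log2(P[i][l] / tot)
        for i in range(ng)
        for l in range(lmax)
        if P[i][l] > 0
    )
    f[prefix_map["lgl"]] = sum(
        P[i][l] / (i + 1) ** 2 for i in range(ng) for l in range(lmax)
    ) / tot
    f[prefix_map["hgl"]] = sum(
        P[i][l] * (i + 1) ** 2 for i in range(ng) for l in range(lmax)
    ) / tot
    f[prefix_map["slgl"]] = sum(
        P[i][l] / ((i + 1) ** 2 * (l + 1) ** 2) for i in range(ng) for l in range(lmax)
    ) / tot
    f[prefix_map["shgl"]] = sum(
        P[i][l] * (i + 1) ** 2 / (l + 1) ** 2 for i in range(ng) for l in range(lmax)
    ) / tot
    f[prefix_map["llgl"]] = sum(
        P[i][l] * (l + 1) ** 2 / (i + 1) ** 2 for i in range(ng) for l in range(lmax)
    ) / tot
    f[prefix_map["lhgl"]] = sum(
        P[i][l] * (i + 1) ** 2 * (l + 1) ** 2 for i in range(ng) for l in range(lmax)
    ) / tot
    return f


GLRLM_MAP = {
    "short": "short_run_emphasis", "long": "long_run_emphasis",
    "gln": "gray_level_nonuniformity", "glnn": "gray_level_nonuniformity_normalized",
    "rln": "run_length_nonuniformity", "rlnn": "run_length_nonuniformity_normalized",
    "pct": "run_percentage", "glv": "gray_level_variance", "lv": "run_variance",
    "entropy": "run_entropy", "lgl": "low_gray_level_run_emphasis",
    "hgl": "high_gray_level_run_emphasis", "slgl": "short_run_low_gray_level_emphasis",
    "shgl": "short_run_high_gray_level_emphasis", "llgl": "long_run_low_gray_level_emphasis",
    "lhgl": "long_run_high_gray_level_emphasis",
}

GLSZM_MAP = {
    "short": "small_area_emphasis", "long": "large_area_emphasis",
    "gln": "gray_level_nonuniformity", "glnn": "gray_level_nonuniformity_normalized",
    "rln": "size_zone_nonuniformity", "rlnn": "size_zone_nonuniformity_normalized",
    "pct": "zone_percentage", "glv": "gray_level_variance", "lv": "zone_variance",
    "entropy": "zone_entropy", "lgl": "low_gray_level_zone_emphasis",
    "hgl": "high_gray_level_zone_emphasis", "slgl": "small_area_low_gray_level_emphasis",
    "shgl": "small_area_high_gray_level_emphasis", "llgl": "large_area_low_gray_level_emphasis",
    "lhgl": "large_area_high_gray_level_emphasis",
}


def oracle_glszm_matrix(g: np.ndarray) -> np.ndarray:
    ng = int(g.max())
    seen = np.zeros(g.shape, dtype=bool)
    zones = []
    for idx in np.argwhere(g > 0):
        idx = tuple(idx)
        if seen[idx]:
            continue
        lvl = g[idx]
        stack = [idx]
        seen[idx] = True
        size = 0
        while stack:
            cur = stack.pop()
            size += 1
            for off in NEIGHBORS_26:
                nb = tuple(np.asarray(cur) + off)
                if _in(g.shape, nb) and not seen[nb] and g[nb] == lvl:
                    seen[nb] = True
                    stack.append(nb)
        zones.append((lvl, size))
    smax = max(s for _, s in zones)
    P = np.zeros((ng, smax))
    for lvl, s in zones:
        P[lvl - 1, s - 1] += 1
    return P


def oracle_gldm_matrix(g: np.ndarray, alpha: float = 0.0) -> np.ndarray:
    ng = int(g.max())
    entries = []
    for idx in np.argwhere(g > 0):
        idx = tuple(idx)
        dep = 0
        for off in NEIGHBORS_26:
            nb = tuple(np.asarray(idx) + off)
            if _in(g.shape, nb) and g[nb] > 0 and abs(g[nb] - g[idx]) <= alpha:
                dep += 1
        entries.append((g[idx], dep + 1))
    jmax = max(j for _, j in entries)
    P = np.zeros((ng, jmax))
    for lvl, j in entries:
        P[lvl - 1, j - 1] += 1
    return P


GLDM_MAP = {
    "short": "small_dependence_emphasis", "long": "large_dependence_emphasis",
    "gln": "gray_level_nonuniformity", "rln": "dependence_nonuniformity",
    "rlnn": "dependence_nonuniformity_normalized", "glv": "gray_level_variance",
    "lv": "dependence_variance", "entropy": "dependence_entropy",
    "lgl": "low_gray_level_emphasis", "hgl": "high_gray_level_emphasis",
    "slgl": "small_dependence_low_gray_level_emphasis",
    "shgl": "small_dependence_high_gray_level_emphasis",
    "llgl": "large_dependence_low_gray_level_emphasis",
    "lhgl": "large_dependence_high_gray_level_emphasis",
}


def oracle_gldm_features(P: np.ndarray) -> dict[str, float]:
    full = _weighted_matrix_features(P, int(P.sum()), "i", "j", dict(GLDM_MAP, glnn="_drop",
                                                                      pct="_drop2"))
    return {k: v for k, v in full.items() if not k.startswith("_drop")}


def oracle_ngtdm(g: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ng = int(g.max())
    n = np.zeros(ng)
    s = np.zeros(ng)
    for idx in np.argwhere(g > 0):
        idx = tuple(idx)
        vals = []
        for off in NEIGHBORS_26:
            nb = tuple(np.asarray(idx) + off)
            if _in(g.shape, nb) and g[nb] > 0:
                vals.append(g[nb])
        if not vals:
            continue
        n[g[idx] - 1] += 1
        s[g[idx] - 1] += abs(g[idx] - sum(vals) / len(vals))
    return n, s


def oracle_ngtdm_features(n: np.ndarray, s: np.ndarray) -> dict[str, float]:
    N = n.sum()
    ng = len(n)
    p = n / N
    present = [i for i in range(ng) if p[i] > 0]
    ngp = len(present)
    denom = sum(p[i] * s[i] for i in range(ng))
    f = {"coarseness": min(1e6, 1.0 / denom) if denom > 0 else 1e6}
    if ngp > 1:
        f["contrast"] = (
            sum(p[i] * p[j] * (i - j) ** 2 for i in present for j in present)
            / (ngp * (ngp - 1))
        ) * (s.sum() / N)
        bd = sum(abs((i + 1) * p[i] - (j + 1) * p[j]) for i in present for j in present)
        f["busyness"] = denom / bd if bd > 0 else 0.0
        f["complexity"] = (
            sum(
                abs(i - j) * (p[i] * s[i] + p[j] * s[j]) / (p[i] + p[j])
                for i in present
                for j in present
            )
            / N
        )
        ssum = s.sum()
        f["strength"] = (
            sum((p[i] + p[j]) * (i - j) ** 2 for i in present for j in present) / ssum
            if ssum > 0
            else 0.0
        )
    else:
        f.update(contrast=0.0, busyness=0.0, complexity=0.0, strength=0.0)
    return f


# --------------------------------------------------------------- mRMR

def oracle_mi(a, b) -> float:
    """Plug-in mutual information from joint counts (nats)."""
    a = list(a)
    b = list(b)
    n = len(a)
    joint = defaultdict(int)
    ca = defaultdict(int)
    cb = defaultdict(int)
    for x, y in zip(a, b):
        joint[(x, y)] += 1
        ca[x] += 1
        cb[y] += 1
    mi = 0.0
    for (x, y), c in joint.items():
        mi += (c / n) * math.log((c * n) / (ca[x] * cb[y]))
    return mi
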