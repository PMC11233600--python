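"""Analysis-region construction: peritumoral shells and intratumoral habitats.

Two derived region families supplement the segmented tumor:

* **peritumoral shells** — morphological dilation of the ROI by a physical
  radius (anisotropy-aware Euclidean distance between voxel centers),
  minus the ROI itself; radii of 1, 3 and 5 mm are the standard set;
* **habitats** — phenotypically distinct tumor subregions obtained by
  K-means clustering of a 13-channel per-voxel local-statistics map
  computed over a 3x3x3 moving window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from sklearn.cluster import KMeans

from .volume import AnnotatedVolume

__all__ = [
    "RegionSet",
    "LocalFeatureMap",
    "LOCAL_CHANNELS",
    "SHELL_RADII_MM",
    "dilate_roi",
    "peritumoral_shell",
    "local_feature_map",
    "kmeans_habitats",
    "build_region_set",
]

SHELL_RADII_MM = (1.0, 3.0, 5.0)

#: The default 13 per-voxel local-statistics channels.
LOCAL_CHANNELS = (
    "mean",
    "median",
    "minimum",
    "maximum",
    "range",
    "variance",
    "std",
    "skewness",
    "kurtosis",
    "energy",
    "entropy",
    "uniformity",
    "cv",
)

#: Bin width (HU) for the windowed entropy/uniformity histogram, anchored
#: at the window minimum so the channels are shift-invariant.
LOCAL_ENTROPY_BIN_HU = 25.0

#: Channels the habitat K-means consumes by default: the shift-equivariant
#: location statistics. Dispersion-type channels (variance, entropy, ...)
#: respond to plateau *interfaces* rather than tissue level — clustering
#: on them carves out spurious boundary habitats and breaks both exact
#: partition recovery and shift invariance, so they are emitted in the
#: map but excluded from the clustering by default.
CLUSTER_CHANNELS = ("mean", "median", "minimum", "maximum")


@dataclass
class LocalFeatureMap:
    """Per-voxel local statistics for the in-tumor voxels.

    ``values`` has shape (n_channels, n_tumor_voxels); ``voxel_index``
    holds the flat indices of those voxels in the source grid.
    """

    channel_names: tuple[str, ...]
    values: np.ndarray
    voxel_index: np.ndarray
    grid_shape: tuple[int, int, int]

    @property
    def n_channels(self) -> int:
        return len(self.channel_names)


@dataclass
class RegionSet:
    """Derived label maps for one sample."""

    tumor_mask: np.ndarray
    shells: dict[float, np.ndarray]
    habitat_labels: np.ndarray  # 0 outside tumor, 1..k inside
    n_habitats: int

    def habitat_mask(self, label: int) -> np.ndarray:
        return self.habitat_labels == label

    def region_masks(self) -> dict[str, np.ndarray]:
        """All named region masks (intra, peri<r>, habitat<j>)."""
        out = {"intra": self.tumor_mask}
        for r, m in self.shells.items():
            out[f"peri{int(r)}"] = m
        for j in range(1, self.n_habitats + 1):
            out[f"habitat{j}"] = self.habitat_mask(j)
        return out


def dilate_roi(mask: np.ndarray, spacing_mm, radius_mm: float) -> np.ndarray:
    """Dilate a binary mask by a physical radius.

    A voxel belongs to the output iff its center lies within
    ``radius_mm`` (Euclidean, in mm, anisotropy-aware) of the center of
    some mask voxel — computed exactly via the Euclidean distance
    transform of the mask complement.
    """
    if radius_mm <= 0:
        raise ValueError("radius_mm must be positive")
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("cannot dilate an empty mask")
    dist = ndimage.distance_transform_edt(~mask, sampling=tuple(spacing_mm))
    out = dist <= radius_mm
    border = np.zeros_like(out)
    for ax in range(3):
        sl = [slice(None)] * 3
        for edge in (0, -1):
            sl[ax] = edge
            border[tuple(sl)] = True
    if (out & border).any():
        warnings.warn(
            f"dilation by {radius_mm} mm reaches the grid boundary "
            f"({int((out & border).sum())} boundary voxels); the shell is clipped",
            stacklevel=2,
        )
    return out


def peritumoral_shell(mask: np.ndarray, spacing_mm, radius_mm: float) -> np.ndarray:
    """Peritumoral shell: dilation by ``radius_mm`` minus the tumor itself."""
    shell = dilate_roi(mask, spacing_mm, radius_mm) & ~np.asarray(mask, dtype=bool)
    if not shell.any():
        raise ValueError(f"peritumoral shell at {radius_mm} mm is empty (mask fills the grid)")
    return shell


def _window_stack(intensities: np.ndarray, flat_idx: np.ndarray) -> np.ndarray:
    """27 x n array of the 3x3x3 neighborhood of each voxel, NaN off-grid."""
    shape = intensities.shape
    coords = np.unravel_index(flat_idx, shape)
    coords = np.stack(coords, axis=1)  # n x 3
    offsets = np.array([(i, j, k) for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)])
    stack = np.full((27, len(flat_idx)), np.nan)
    for w, off in enumerate(offsets):
        nb = coords + off
        ok = np.all((nb >= 0) & (nb < np.asarray(shape)), axis=1)
        stack[w, ok] = intensities[nb[ok, 0], nb[ok, 1], nb[ok, 2]]
    return stack


def local_feature_map(
    vol: AnnotatedVolume,
    channels=LOCAL_CHANNELS,
    restrict_to_mask: bool = True,
) -> LocalFeatureMap:
    """13-channel local-statistics map over 3x3x3 windows, per tumor voxel.

    Windows are truncated at the grid boundary, and — by default — to
    in-ROI voxels, so habitat statistics describe tumor tissue rather
    than the surrounding lung background (set ``restrict_to_mask=False``
    to use the full in-grid window). The entropy/uniformity histogram
    uses a fixed 25 HU bin width anchored at the window minimum, so every
    channel is invariant to a global intensity shift up to the z-scoring
    applied later.
    """
    if not vol.mask.any():
        raise ValueError("tumor mask is empty")
    flat_idx = np.flatnonzero(vol.mask.ravel())
    stack = _window_stack(vol.intensities, flat_idx)
    if restrict_to_mask:
        in_mask = _window_stack(vol.mask.astype(np.float64), flat_idx)
        stack[in_mask != 1.0] = np.nan

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        n = np.sum(~np.isnan(stack), axis=0).astype(float)
        mean = np.nanmean(stack, axis=0)
        med = np.nanmedian(stack, axis=0)
        mn = np.nanmin(stack, axis=0)
        mx = np.nanmax(stack, axis=0)
        var = np.nanvar(stack, axis=0)
        std = np.sqrt(var)
        centered = stack - mean
        m3 = np.nansum(centered**3, axis=0) / n
        m4 = np.nansum(centered**4, axis=0) / n
        nz = std > 1e-12
        skew = np.zeros_like(mean)
        kurt = np.zeros_like(mean)
        skew[nz] = m3[nz] / std[nz] ** 3
        kurt[nz] = m4[nz] / var[nz] ** 2
        energy = np.nansum(stack**2, axis=0)

        binned = np.floor((stack - mn[None, :]) / LOCAL_ENTROPY_BIN_HU)
        entropy = np.zeros_like(mean)
        uniformity = np.zeros_like(mean)
        srt = np.sort(binned, axis=0)  # NaNs sort to the end
        for col in range(srt.shape[1]):
            vals = srt[: int(n[col]), col]
            _, counts = np.unique(vals, return_counts=True)
            p = counts / counts.sum()
            entropy[col] = -np.sum(p * np.log2(p))
            uniformity[col] = np.sum(p * p)

        cv = np.zeros_like(mean)
        nzmean = np.abs(mean) > 1e-12
        cv[nzmean] = std[nzmean] / np.abs(mean[nzmean])

    table = {
        "mean": mean, "median": med, "minimum": mn, "maximum": mx, "range": mx - mn,
        "variance": var, "std": std, "skewness": skew, "kurtosis": kurt,
        "energy": energy, "entropy": entropy, "uniformity": uniformity, "cv": cv,
    }
    values = np.stack([table[c] for c in channels])
    return LocalFeatureMap(tuple(channels), values, flat_idx, vol.shape)


def kmeans_habitats(
    fmap: LocalFeatureMap,
    k: int = 3,
    seed: int = 0,
    cluster_channels: tuple[str, ...] | None = CLUSTER_CHANNELS,
) -> np.ndarray:
    """Cluster the local-feature map into k habitats.

    By default only the location channels in :data:`CLUSTER_CHANNELS`
    enter the clustering (pass ``cluster_channels=None`` to use every
    channel of the map). Channels are z-scored across tumor voxels
    (zero-variance channels are dropped); K-means uses k-means++ with 10
    restarts at tol 1e-6. Labels are renumbered in increasing order of
    the cluster-mean local intensity (the 'mean' channel, or the first
    channel if absent) so the numbering is deterministic. Returns an
    integer grid: 0 outside the tumor, 1..k inside.
    """
    n_vox = fmap.values.shape[1]
    if n_vox < k:
        raise ValueError(f"only {n_vox} tumor voxels but k={k} habitats requested")
    if cluster_channels is None:
        use = list(range(fmap.n_channels))
    else:
        use = [fmap.channel_names.index(c) for c in cluster_channels if c in fmap.channel_names]
        if not use:
            use = list(range(fmap.n_channels))
    X = fmap.values[use].T.astype(np.float64)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    keep = sd > 1e-12
    if keep.any():
        Z = (X[:, keep] - mu[keep]) / sd[keep]
    else:  # fully degenerate map: a single habitat
        Z = np.zeros((n_vox, 1))
    km = KMeans(n_clusters=k, init="k-means++", n_init=10, tol=1e-6, random_state=seed)
    raw = km.fit_predict(Z)

    order_channel = "mean" if "mean" in fmap.channel_names else fmap.channel_names[0]
    ref = fmap.values[fmap.channel_names.index(order_channel)]
    means = np.array([ref[raw == j].mean() if (raw == j).any() else np.inf for j in range(k)])
    empty = [j for j in range(k) if not (raw == j).any()]
    if empty:
        warnings.warn(f"{len(empty)} habitat cluster(s) empty", stacklevel=2)
    rank = np.argsort(np.argsort(means, kind="stable"), kind="stable")

    labels = np.zeros(fmap.grid_shape, dtype=np.int32)
    labels.ravel()[fmap.voxel_index] = rank[raw] + 1
    return labels


def build_region_set(
    vol: AnnotatedVolume,
    shell_radii_mm=SHELL_RADII_MM,
    k: int = 3,
    seed: int = 0,
    channels=LOCAL_CHANNELS,
    cluster_channels: tuple[str, ...] | None = CLUSTER_CHANNELS,
) -> RegionSet:
    """Tumor + peritumoral shells + habitat labels for one sample."""
    fmap = local_feature_map(vol, channels)
    habitats = kmeans_habitats(fmap, k=k, seed=seed, cluster_channels=cluster_channels)
    shells = {float(r): peritumoral_shell(vol.mask, vol.spacing_mm, r) for r in shell_radii_mm}
    return RegionSet(vol.mask.copy(), shells, habitats, k)
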