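"""Assembling the per-sample / per-cohort feature tables.

Feature columns are named ``region|transform|family|name`` — e.g.
``intra|original|firstorder|mean`` or ``habitat2|wavelet-LHH|glcm|contrast``.
Shape features are geometry-only and appear under the original transform
only. Habitat features are the per-habitat bank concatenated over
habitats 1..k with region-tag provenance.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from ..regions import RegionSet
from ..volume import AnnotatedVolume
from .discretize import DiscretizationSpec
from .firstorder import first_order_features
from .shape import shape_features
from .texture import texture_features
from .transforms import transform_bank

__all__ = ["extract_region_features", "extract_sample_features", "extract_cohort_features", "tidy_table"]


def extract_region_features(
    vol: AnnotatedVolume,
    region_mask: np.ndarray,
    region_tag: str,
    disc: DiscretizationSpec = DiscretizationSpec(),
    transforms: dict[str, np.ndarray] | None = None,
    include_shape: bool = True,
) -> dict[str, float]:
    """Full feature bank of one region; keys carry full provenance."""
    region_mask = np.asarray(region_mask, dtype=bool)
    out: dict[str, float] = {}
    if not region_mask.any():
        # empty habitat clusters are legal; emit a zeroed bank so the
        # table stays rectangular, and flag it
        warnings.warn(f"region {region_tag} is empty; features zeroed", stacklevel=2)
        ref = extract_region_features(
            vol, vol.mask, region_tag, disc, transforms, include_shape
        )
        return {k: 0.0 for k in ref}

    if transforms is None:
        transforms = transform_bank(vol)

    if include_shape:
        for name, value in shape_features(region_mask, vol.spacing_mm).items():
            out[f"{region_tag}|original|shape|{name}"] = value

    for tag, image in transforms.items():
        fo = first_order_features(image[region_mask], vol.voxel_volume_mm3, disc)
        for name, value in fo.items():
            out[f"{region_tag}|{tag}|firstorder|{name}"] = value
        tex = texture_features(image, region_mask, disc)
        for family, feats in tex.items():
            for name, value in feats.items():
                out[f"{region_tag}|{tag}|{family}|{name}"] = value
    return out


def extract_sample_features(
    vol: AnnotatedVolume,
    regions: RegionSet,
    disc: DiscretizationSpec = DiscretizationSpec(),
    log_sigmas_mm=(1.0, 3.0),
    wavelet: str | None = "coif1",
    region_tags: tuple[str, ...] | None = None,
) -> pd.Series:
    """Feature bank over every region of one sample, as a named Series."""
    transforms = transform_bank(vol, log_sigmas_mm, wavelet)
    values: dict[str, float] = {}
    masks = regions.region_masks()
    for tag, mask in masks.items():
        if region_tags is not None and tag not in region_tags:
            continue
        values.update(extract_region_features(vol, mask, tag, disc, transforms))
    name = vol.meta.get("sample_id")
    return pd.Series(values, name=name)


def extract_cohort_features(
    samples: list[tuple[AnnotatedVolume, RegionSet]],
    disc: DiscretizationSpec = DiscretizationSpec(),
    log_sigmas_mm=(1.0, 3.0),
    wavelet: str | None = "coif1",
    region_tags: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Wide feature table: one row per sample, one column per feature."""
    rows = [
        extract_sample_features(vol, regions, disc, log_sigmas_mm, wavelet, region_tags)
        for vol, regions in samples
    ]
    return pd.DataFrame(rows)


def tidy_table(wide: pd.DataFrame) -> pd.DataFrame:
    """Long-form view: sample_id, region, transform, family, name, value."""
    long = wide.stack().rename("value").reset_index()
    long.columns = ["sample_id", "feature", "value"]
    parts = long["feature"].str.split("|", expand=True)
    parts.columns = ["region", "transform", "family", "name"]
    return pd.concat([long[["sample_id"]], parts, long[["value"]]], axis=1)
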