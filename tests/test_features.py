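"""Feature-bank correctness: worked examples, invariances, and full
brute-force oracle equivalence on random 5^3 images."""

import math

import numpy as np
import pytest

from habitatrad.features import (
    DiscretizationSpec,
    FIRSTORDER_NAMES,
    SHAPE_NAMES,
    TEXTURE_FAMILY_SIZES,
    first_order_features,
    shape_features,
    texture_features,
    transform_bank,
)
from habitatrad.features.texture import (
    DIRECTIONS_13,
    glcm_matrix,
    glcm_features_from_matrix,
    glrlm_matrix,
    glszm_matrix,
    gldm_matrix,
    ngtdm_matrix,
    _label_grid,
)
from habitatrad.synthetic import PhantomSpec, generate_phantom
from habitatrad.volume import AnnotatedVolume

import oracles


UNIT = DiscretizationSpec()


# ------------------------------------------------------------ first order

def test_first_order_worked_example():
    vals = np.array([1.0, 2.0, 3.0, 4.0])
    f = first_order_features(vals, 1.0, UNIT)
    assert f["mean"] == pytest.approx(2.5)
    assert f["energy"] == pytest.approx(30.0)
    assert len(f) == 18
    assert set(f) == set(FIRSTORDER_NAMES)


def test_first_order_entropy_uniformity_equiprobable_bins():
    # four values, one per 25-HU bin -> 2 bits, uniformity 1/4
    vals = np.array([0.0, 25.0, 50.0, 75.0])
    f = first_order_features(vals, 1.0, UNIT)
    assert f["entropy"] == pytest.approx(2.0)
    assert f["uniformity"] == pytest.approx(0.25)


def test_first_order_constant_region_conventions():
    f = first_order_features(np.full(40, 7.0), 1.0, UNIT)
    assert f["skewness"] == 0.0 and f["kurtosis"] == 0.0
    assert f["entropy"] == 0.0 and f["uniformity"] == 1.0
    assert all(np.isfinite(v) for v in f.values())


def test_first_order_shift_and_scale_equivariance():
    rng = np.random.default_rng(3)
    vals = rng.normal(50, 20, size=200)
    base = first_order_features(vals, 1.0, UNIT)
    shifted = first_order_features(vals + 10.0, 1.0, UNIT)
    scaled = first_order_features(vals * 2.0, 1.0, UNIT)
    assert shifted["mean"] == pytest.approx(base["mean"] + 10.0)
    assert shifted["variance"] == pytest.approx(base["variance"])
    assert scaled["energy"] == pytest.approx(base["energy"] * 4.0)


# ------------------------------------------------------------------ shape

def test_shape_count_and_sphere_volume():
    spec = PhantomSpec(grid_shape=(11, 11, 11), spacing_mm=(1, 1, 1), nodule_radius_mm=3,
                       n_plateaus=1, plateau_levels=(0.0,), noise_sd=0.0)
    vol = generate_phantom(spec, 0)
    f = shape_features(vol.mask, vol.spacing_mm)
    assert set(f) == set(SHAPE_NAMES) and len(f) == 14
    assert f["voxel_volume"] == pytest.approx(123.0)  # lattice ball r=3


@pytest.mark.parametrize("radius", [5, 10, 20])
def test_sphericity_approaches_one_from_below(radius):
    n = 2 * radius + 5
    spec = PhantomSpec(grid_shape=(n, n, n), spacing_mm=(1, 1, 1), nodule_radius_mm=radius,
                       n_plateaus=1, plateau_levels=(0.0,), noise_sd=0.0)
    vol = generate_phantom(spec, 0)
    s = shape_features(vol.mask, vol.spacing_mm)["sphericity"]
    assert 0.9 < s < 1.0


def test_sphericity_monotone_in_radius():
    values = []
    for radius in (5, 10, 20):
        n = 2 * radius + 5
        spec = PhantomSpec(grid_shape=(n, n, n), spacing_mm=(1, 1, 1), nodule_radius_mm=radius,
                           n_plateaus=1, plateau_levels=(0.0,), noise_sd=0.0)
        vol = generate_phantom(spec, 0)
        values.append(shape_features(vol.mask, vol.spacing_mm)["sphericity"])
    assert values[0] < values[1] < values[2]


def test_shape_single_voxel_degenerate_but_finite():
    mask = np.zeros((5, 5, 5), dtype=bool)
    mask[2, 2, 2] = True
    with pytest.warns(UserWarning):
        f = shape_features(mask, (1, 1, 1))
    assert all(np.isfinite(v) for v in f.values())


def test_shape_intensity_independent():
    # shape features read only the mask; ensured by signature (no intensity arg)
    mask = np.zeros((7, 7, 7), dtype=bool)
    mask[2:5, 2:5, 2:5] = True
    f1 = shape_features(mask, (1, 1, 1))
    f2 = shape_features(mask.copy(), (1, 1, 1))
    assert f1 == f2


# ---------------------------------------------------------------- texture

def test_texture_family_sizes_sum_to_75():
    assert sum(TEXTURE_FAMILY_SIZES.values()) == 75
    img = np.random.default_rng(0).integers(0, 4, (6, 6, 6)).astype(float) * 25
    fams = texture_features(img, np.ones((6, 6, 6), bool), UNIT)
    for fam, size in TEXTURE_FAMILY_SIZES.items():
        assert len(fams[fam]) == size


def test_glcm_two_row_image_has_zero_contrast():
    # [[1,1],[2,2]] with the horizontal offset pairs only (1,1) and (2,2)
    g = np.array([[1, 1], [2, 2]]).reshape(2, 2, 1)
    P = glcm_matrix(g, (0, 1, 0))
    feats = glcm_features_from_matrix(P)
    assert feats["contrast"] == 0.0


def test_constant_region_texture_conventions():
    img = np.full((5, 5, 5), 42.0)
    fams = texture_features(img, np.ones((5, 5, 5), bool), UNIT)
    assert fams["glcm"]["contrast"] == 0.0
    assert fams["glcm"]["correlation"] == 1.0
    assert fams["ngtdm"]["coarseness"] == 1e6


def test_texture_deterministic():
    rng = np.random.default_rng(5)
    img = rng.normal(size=(6, 6, 6)) * 100
    mask = rng.random((6, 6, 6)) < 0.8
    a = texture_features(img, mask, UNIT)
    b = texture_features(img, mask, UNIT)
    assert a == b


def _oracle_first_order(vals, width=25.0):
    n = len(vals)
    mean = sum(vals) / n
    var = sum((v - mean) ** 2 for v in vals) / n
    sd = math.sqrt(var)
    g = oracles.discretize_fbw(vals, width)
    counts = {}
    for x in g:
        counts[x] = counts.get(x, 0) + 1
    probs = [c / n for c in counts.values()]
    srt = sorted(vals)
    p10, p25, p75, p90 = (np.percentile(vals, q) for q in (10, 25, 75, 90))
    robust = [v for v in vals if p10 <= v <= p90]
    rmean = sum(robust) / len(robust)
    return {
        "energy": sum(v * v for v in vals),
        "total_energy": sum(v * v for v in vals),
        "entropy": -sum(p * math.log2(p) for p in probs),
        "minimum": min(vals),
        "percentile10": p10,
        "percentile90": p90,
        "maximum": max(vals),
        "mean": mean,
        "median": float(np.median(srt)),
        "interquartile_range": p75 - p25,
        "range": max(vals) - min(vals),
        "mean_absolute_deviation": sum(abs(v - mean) for v in vals) / n,
        "robust_mean_absolute_deviation": sum(abs(v - rmean) for v in robust) / len(robust),
        "root_mean_squared": math.sqrt(sum(v * v for v in vals) / n),
        "skewness": sum((v - mean) ** 3 for v in vals) / n / sd**3 if sd > 0 else 0.0,
        "kurtosis": sum((v - mean) ** 4 for v in vals) / n / var**2 if sd > 0 else 0.0,
        "variance": var,
        "uniformity": sum(p * p for p in probs),
    }


def test_every_feature_matches_brute_force_oracle(small_random_images):
    """All 18 + 75 features equal literal-formula oracles, tol 1e-9."""
    for img, mask in small_random_images:
        fo = first_order_features(img[mask], 1.0, UNIT)
        oracle_fo = _oracle_first_order(list(img[mask]))
        for name in FIRSTORDER_NAMES:
            assert fo[name] == pytest.approx(oracle_fo[name], abs=1e-9), name

        fams = texture_features(img, mask, UNIT)
        g = _label_grid(img, mask, UNIT)
        n_vox = int(mask.sum())

        per_dir = []
        for d in DIRECTIONS_13:
            P = oracles.oracle_glcm_matrix(g, d)
            assert np.array_equal(P, glcm_matrix(g, d))
            if P.sum() > 0:
                per_dir.append(oracles.oracle_glcm_features(P))
        for name in fams["glcm"]:
            expect = sum(f[name] for f in per_dir) / len(per_dir)
            assert fams["glcm"][name] == pytest.approx(expect, abs=1e-9), f"glcm {name}"

        per_dir = []
        for d in DIRECTIONS_13:
            P = oracles.oracle_glrlm_matrix(g, d)
            assert np.array_equal(P, glrlm_matrix(g, d))
            per_dir.append(oracles._weighted_matrix_features(P, n_vox, "i", "l",
                                                             oracles.GLRLM_MAP))
        for name in fams["glrlm"]:
            expect = sum(f[name] for f in per_dir) / len(per_dir)
            assert fams["glrlm"][name] == pytest.approx(expect, abs=1e-9), f"glrlm {name}"

        P = oracles.oracle_glszm_matrix(g)
        assert np.array_equal(P, glszm_matrix(g))
        expect = oracles._weighted_matrix_features(P, n_vox, "i", "s", oracles.GLSZM_MAP)
        for name in fams["glszm"]:
            assert fams["glszm"][name] == pytest.approx(expect[name], abs=1e-9), f"glszm {name}"

        P = oracles.oracle_gldm_matrix(g)
        assert np.array_equal(P, gldm_matrix(g))
        expect = oracles.oracle_gldm_features(P)
        for name in fams["gldm"]:
            assert fams["gldm"][name] == pytest.approx(expect[name], abs=1e-9), f"gldm {name}"

        n_, s_ = oracles.oracle_ngtdm(g)
        ni, si = ngtdm_matrix(g)
        assert np.allclose(n_, ni) and np.allclose(s_, si)
        expect = oracles.oracle_ngtdm_features(n_, s_)
        for name in fams["ngtdm"]:
            assert fams["ngtdm"][name] == pytest.approx(expect[name], abs=1e-9), f"ngtdm {name}"


# ------------------------------------------------------------- transforms

def test_wavelet_bank_has_eight_aligned_subbands():
    spec = PhantomSpec(grid_shape=(20, 20, 20), nodule_radius_mm=6.0,
                       n_plateaus=1, plateau_levels=(0.0,))
    vol = generate_phantom(spec, 0)
    bank = transform_bank(vol, log_sigmas_mm=(), wavelet="coif1")
    tags = [t for t in bank if t.startswith("wavelet-")]
    assert len(tags) == 8
    assert sorted(tags) == sorted(
        f"wavelet-{a}{b}{c}" for a in "LH" for b in "LH" for c in "LH"
    )
    assert all(bank[t].shape == vol.shape for t in tags)


def test_log_of_constant_image_is_zero():
    vol = AnnotatedVolume(np.full((12, 12, 12), 5.0), (1, 1, 1), np.ones((12, 12, 12), bool))
    bank = transform_bank(vol, log_sigmas_mm=(2.0,), wavelet=None)
    assert np.allclose(bank["log-sigma-2mm"], 0.0, atol=1e-9)


def test_log_scale_selection_peaks_at_matched_sigma():
    # Gaussian blob of scale sigma responds most strongly near filter sigma
    x = np.arange(31) - 15.0
    X, Y, Z = np.meshgrid(x, x, x, indexing="ij")
    blob_sigma = 3.0
    img = np.exp(-(X**2 + Y**2 + Z**2) / (2 * blob_sigma**2))
    vol = AnnotatedVolume(img, (1, 1, 1), np.ones(img.shape, bool))
    responses = {}
    for s in (1.0, 3.0, 9.0):
        bank = transform_bank(vol, log_sigmas_mm=(s,), wavelet=None)
        # normalized response |sigma^2 LoG| at the blob center
        responses[s] = abs(s**2 * bank[f"log-sigma-{s:g}mm"][15, 15, 15])
    assert responses[3.0] > responses[1.0]
    assert responses[3.0] > responses[9.0]


def test_oversized_log_sigma_skipped_with_warning():
    spec = PhantomSpec(grid_shape=(16, 16, 16), nodule_radius_mm=4.0,
                       n_plateaus=1, plateau_levels=(0.0,))
    vol = generate_phantom(spec, 0)
    with pytest.warns(UserWarning, match="skipped"):
        bank = transform_bank(vol, log_sigmas_mm=(50.0,), wavelet=None)
    assert "log-sigma-50mm" not in bank
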