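"""ROC/AUC, DeLong, Hosmer–Lemeshow, decision curves, cosine schedule."""

import numpy as np
import pytest
from scipy.special import expit
from scipy.stats import norm

from habitatrad.evaluation import (
    LRScheduleParams,
    auc_mann_whitney,
    calibration_bins,
    cosine_lr,
    decision_curve,
    delong_test,
    evaluate_models,
    hosmer_lemeshow,
    operating_point,
    roc_auc,
)

import oracles


# ------------------------------------------------------------------- AUC

def test_auc_worked_example():
    assert auc_mann_whitney([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == pytest.approx(0.75)


def test_auc_perfect_separation():
    assert auc_mann_whitney([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0


def test_auc_label_flip_antisymmetry():
    rng = np.random.default_rng(0)
    s = rng.normal(size=40)
    y = rng.integers(0, 2, 40)
    if y.min() == y.max():
        y[0] = 1 - y[0]
    assert auc_mann_whitney(s, 1 - y) == pytest.approx(1 - auc_mann_whitney(s, y))


def test_auc_matches_all_pairs_oracle():
    rng = np.random.default_rng(1)
    for _ in range(100):
        n = rng.integers(6, 51)
        s = np.round(rng.normal(size=n), 1)  # rounding forces ties
        y = rng.integers(0, 2, n)
        if y.min() == y.max():
            y[0] = 1 - y[0]
        assert auc_mann_whitney(s, y) == pytest.approx(oracles.brute_auc(s, y), abs=1e-12)


def test_auc_single_class_rejected():
    with pytest.raises(ValueError, match="classes"):
        roc_auc([0.1, 0.9], [1, 1])


def test_delong_ci_coverage_binormal():
    # binormal model with true AUC Phi(mu/sqrt(2))
    mu = 1.0
    true_auc = norm.cdf(mu / np.sqrt(2))
    rng = np.random.default_rng(2)
    covered = 0
    reps = 500
    for _ in range(reps):
        neg = rng.normal(0, 1, 100)
        pos = rng.normal(mu, 1, 100)
        s = np.r_[neg, pos]
        y = np.r_[np.zeros(100), np.ones(100)]
        _, (lo, hi) = roc_auc(s, y)
        covered += lo <= true_auc <= hi
    assert covered / reps == pytest.approx(0.95, abs=0.03)


# ---------------------------------------------------------------- DeLong

def test_delong_self_comparison_is_null():
    rng = np.random.default_rng(3)
    s = rng.normal(size=60)
    y = rng.integers(0, 2, 60)
    y[:2] = [0, 1]
    z, p = delong_test(s, s.copy(), y)
    assert z == 0.0 and p == 1.0


def test_delong_detects_informative_vs_noise():
    rng = np.random.default_rng(4)
    hits = 0
    for _ in range(100):
        y = np.r_[np.zeros(100), np.ones(100)].astype(int)
        good = y + rng.normal(0, 0.7, 200)
        noise = rng.normal(size=200)
        _, p = delong_test(good, noise, y)
        hits += p < 0.05
    assert hits / 100 > 0.80


def _bootstrap_p(sa, sb, y, n_boot=2000, seed=0):
    rng = np.random.default_rng(seed)
    obs = auc_mann_whitney(sa, y) - auc_mann_whitney(sb, y)
    n = len(y)
    diffs = []
    while len(diffs) < n_boot:
        idx = rng.integers(0, n, n)
        yy = y[idx]
        if yy.min() == yy.max():
            continue
        diffs.append(auc_mann_whitney(sa[idx], yy) - auc_mann_whitney(sb[idx], yy))
    diffs = np.asarray(diffs)
    se = diffs.std(ddof=1)
    return 2 * norm.sf(abs(obs) / se)


def test_delong_p_agrees_with_paired_bootstrap():
    rng = np.random.default_rng(5)
    for seed in range(3):
        y = np.r_[np.zeros(75), np.ones(75)].astype(int)
        sa = y + rng.normal(0, 1.0, 150)
        sb = 0.5 * y + rng.normal(0, 1.0, 150)
        _, p = delong_test(sa, sb, y)
        p_boot = _bootstrap_p(sa, sb, y, seed=seed)
        assert abs(p - p_boot) < 0.02


def test_delong_impossible_pairing_rejected():
    # AUCs 1 and 0 with zero placement variance: no valid pairing exists
    y = np.array([0, 0, 1, 1])
    with pytest.raises(ValueError, match="variance"):
        delong_test(np.array([1.0, 2, 3, 4]), np.array([4.0, 3, 2, 1]), y)


# ------------------------------------------------------- Hosmer–Lemeshow

def test_hl_exact_calibration_gives_zero_chi2():
    probs = np.r_[np.full(50, 0.2), np.full(50, 0.8)]
    labels = np.r_[np.ones(10), np.zeros(40), np.ones(40), np.zeros(10)]
    chi2, df, p = hosmer_lemeshow(probs, labels)
    assert chi2 == pytest.approx(0.0, abs=1e-12)
    assert p == pytest.approx(1.0)


def test_hl_null_rejection_rate_near_alpha():
    # the df = g-2 reference assumes probabilities fitted on the same data,
    # so the calibration null is a fitted logistic model
    import warnings
    import statsmodels.api as sm

    rng = np.random.default_rng(6)
    rejections = 0
    reps = 200
    for _ in range(reps):
        x = rng.normal(size=2000)
        truth = expit(-0.3 + 0.8 * x)
        labels = (rng.random(2000) < truth).astype(int)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(labels, sm.add_constant(x)).fit(disp=0)
        probs = np.clip(fit.predict(sm.add_constant(x)), 1e-9, 1 - 1e-9)
        _, _, p = hosmer_lemeshow(probs, labels)
        rejections += p < 0.05
    assert rejections / reps == pytest.approx(0.05, abs=0.04)


def test_hl_rejects_miscalibration():
    rng = np.random.default_rng(7)
    rejections = 0
    for _ in range(50):
        probs = rng.uniform(0.05, 0.95, 2000)
        labels = (rng.random(2000) < probs).astype(int)
        _, _, p = hosmer_lemeshow(probs**2, labels)
        rejections += p < 0.05
    assert rejections / 50 > 0.80


def test_hl_rejects_bad_probs():
    with pytest.raises(ValueError, match="strictly"):
        hosmer_lemeshow([0.0, 0.5] * 10, [0, 1] * 10)


def test_calibration_bins_monotone_prediction_means():
    rng = np.random.default_rng(8)
    probs = rng.uniform(0.01, 0.99, 500)
    labels = (rng.random(500) < probs).astype(int)
    bins = calibration_bins(probs, labels)
    assert bins["mean_predicted"].is_monotonic_increasing
    assert bins["n"].sum() == 500


# ------------------------------------------------------------------- DCA

def test_treat_all_net_benefit_closed_form():
    y = np.r_[np.ones(50), np.zeros(50)]
    dca = decision_curve({}, y, thresholds=np.array([0.25]))
    assert dca["treat_all"].iloc[0] == pytest.approx(0.5 - 0.5 * (0.25 / 0.75))
    assert dca["treat_all"].iloc[0] == pytest.approx(1.0 / 3.0)


def test_perfect_classifier_net_benefit_is_prevalence():
    y = np.r_[np.ones(30), np.zeros(70)]
    probs = y.astype(float)
    dca = decision_curve({"perfect": probs}, y)
    assert np.allclose(dca["perfect"], 0.3, atol=1e-12)


def test_net_benefit_bounded_by_prevalence():
    rng = np.random.default_rng(9)
    for _ in range(50):
        n = rng.integers(40, 120)
        y = rng.integers(0, 2, n)
        if y.min() == y.max():
            y[0] = 1 - y[0]
        probs = rng.random(n)
        dca = decision_curve({"m": probs}, y)
        assert np.all(dca["m"] <= y.mean() + 1e-12)
        assert np.all(dca["treat_all"] <= y.mean() + 1e-12)


# --------------------------------------------------------- cosine schedule

def test_cosine_schedule_endpoints():
    assert cosine_lr(LRScheduleParams(0.0, 0.01, 100, 0)) == pytest.approx(0.01)
    assert cosine_lr(LRScheduleParams(0.0, 0.01, 100, 100)) == pytest.approx(0.0)
    assert cosine_lr(LRScheduleParams(0.0, 0.01, 100, 50)) == pytest.approx(0.005)


def test_cosine_backbone_frozen_first_half():
    assert cosine_lr(LRScheduleParams(0.0, 0.01, 100, 25, mode="backbone")) == 0.0
    later = cosine_lr(LRScheduleParams(0.0, 0.01, 100, 75, mode="backbone"))
    assert later == pytest.approx(cosine_lr(LRScheduleParams(0.0, 0.01, 100, 75)))


def test_cosine_monotone_non_increasing():
    values = [cosine_lr(LRScheduleParams(0.001, 0.01, 100, t)) for t in range(0, 101, 5)]
    assert all(a >= b - 1e-15 for a, b in zip(values, values[1:]))


def test_cosine_invalid_params_rejected():
    with pytest.raises(ValueError):
        cosine_lr(LRScheduleParams(0.0, 0.01, 0, 0))
    with pytest.raises(ValueError):
        cosine_lr(LRScheduleParams(0.02, 0.01, 10, 0))


# ---------------------------------------------------------------- report

def test_evaluate_models_bundle_consistency():
    rng = np.random.default_rng(10)
    y = np.r_[np.zeros(60), np.ones(60)].astype(int)
    good = expit(2 * (y + rng.normal(0, 0.8, 120)) - 1)
    noise = expit(rng.normal(size=120))
    rep = evaluate_models({"good": good, "noise": noise}, y)
    assert rep.auc["good"] > rep.auc["noise"]
    for name, (lo, hi) in rep.auc_ci.items():
        assert 0 <= lo <= rep.auc[name] <= hi <= 1
    assert rep.delong.loc["good", "noise"] == rep.delong.loc["noise", "good"]
    assert np.allclose(np.diag(rep.delong), 1.0)
    m = rep.metrics["good"]
    assert 0 <= m["sensitivity"] <= 1 and 0 <= m["specificity"] <= 1


def test_operating_point_youden_freeze():
    rng = np.random.default_rng(11)
    y = np.r_[np.zeros(50), np.ones(50)].astype(int)
    s = y + rng.normal(0, 0.5, 100)
    train = operating_point(s, y)
    frozen = operating_point(s, y, threshold=train["threshold"])
    assert frozen == train
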