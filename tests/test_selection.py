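"""Feature-selection cascade: ICC, t-test filter, Pearson de-correlation,
mRMR (with exhaustive oracle), Lasso."""

import numpy as np
import pandas as pd
import pytest

from habitatrad.selection import (
    SelectionReport,
    icc_2_1,
    icc_filter,
    l1_logistic_fit,
    lasso_select,
    mrmr_select,
    pearson_greedy_filter,
    run_cascade,
    standardize_and_ttest,
)

import oracles


def _frame(arr, prefix="f"):
    arr = np.asarray(arr)
    return pd.DataFrame(arr, columns=[f"{prefix}{i}" for i in range(arr.shape[1])])


# ------------------------------------------------------------------- ICC

def test_icc_identical_tables_all_retained():
    rng = np.random.default_rng(0)
    a = _frame(rng.normal(size=(50, 5)))
    survivors = icc_filter(a, a.copy())
    assert survivors == list(a.columns)
    assert icc_2_1(a["f0"], a["f0"]) == pytest.approx(1.0)


def test_icc_variance_ratio_nine_to_one():
    # subject variance 9, error variance 1 -> ICC = 0.9
    rng = np.random.default_rng(1)
    s = rng.normal(0, 3.0, size=500)
    a = s + rng.normal(0, 1.0, size=500)
    b = s + rng.normal(0, 1.0, size=500)
    assert icc_2_1(a, b) == pytest.approx(0.9, abs=0.05)
    survivors = icc_filter(_frame(a[:, None]), _frame(b[:, None]), threshold=0.85)
    assert survivors == ["f0"]


def test_icc_permuted_near_zero_and_dropped():
    rng = np.random.default_rng(2)
    a = rng.normal(size=500)
    b = rng.permutation(a)
    assert abs(icc_2_1(a, b)) < 0.15
    assert icc_filter(_frame(a[:, None]), _frame(b[:, None])) == []


def test_icc_matches_pingouin_oracle():
    pingouin = pytest.importorskip("pingouin")
    rng = np.random.default_rng(3)
    for _ in range(5):
        s = rng.normal(0, 2, 40)
        a = s + rng.normal(0, 1, 40)
        b = 0.5 + s + rng.normal(0, 1, 40)
        df = pd.DataFrame({
            "targets": np.r_[np.arange(40), np.arange(40)],
            "raters": ["A"] * 40 + ["B"] * 40,
            "score": np.r_[a, b],
        })
        ref = pingouin.intraclass_corr(df, "targets", "raters", "score")
        expected = ref.loc[ref["Type"] == "ICC(A,1)", "ICC"].item()
        assert icc_2_1(a, b) == pytest.approx(expected, abs=1e-8)


def test_icc_zero_variance_dropped_with_reason():
    a = _frame(np.ones((30, 1)))
    rep = SelectionReport()
    assert icc_filter(a, a.copy(), report=rep) == []
    assert "f0" in rep.dropped_reasons


# ------------------------------------------------------- z-score + t-test

def test_ttest_type_one_error_near_alpha():
    rng = np.random.default_rng(4)
    rates = []
    for _ in range(200):
        X = _frame(rng.normal(size=(80, 20)))
        y = np.r_[np.ones(40), np.zeros(40)].astype(int)
        survivors, _, _ = standardize_and_ttest(X, y, alpha=0.05)
        rates.append(len(survivors) / 20)
    assert np.mean(rates) == pytest.approx(0.05, abs=0.02)


def test_ttest_detects_large_shift():
    rng = np.random.default_rng(5)
    y = np.r_[np.ones(50), np.zeros(50)].astype(int)
    X = _frame(rng.normal(size=(100, 3)))
    X["f0"] += 2.0 * y  # d = 2 -> power > 99%
    survivors, z, scaler = standardize_and_ttest(X, y)
    assert "f0" in survivors
    assert np.allclose(z.mean(), 0.0, atol=1e-12)
    assert np.allclose(z.std(ddof=0), 1.0, atol=1e-12)


def test_ttest_constant_feature_convention():
    y = np.r_[np.ones(10), np.zeros(10)].astype(int)
    X = _frame(np.ones((20, 1)))
    rep = SelectionReport()
    survivors, _, _ = standardize_and_ttest(X, y, report=rep)
    assert survivors == []
    assert rep.statistics["ttest"]["f0"] == 1.0


# ----------------------------------------------------------- Pearson

def test_pearson_duplicate_column_deduplicated():
    rng = np.random.default_rng(6)
    x = rng.normal(size=100)
    X = pd.DataFrame({"a": x, "b": x.copy(), "c": rng.normal(size=100)})
    survivors = pearson_greedy_filter(X, 0.9)
    assert sorted(survivors)[-1] == "c" and len(survivors) == 2


def test_pearson_independent_features_all_survive():
    rng = np.random.default_rng(7)
    X = _frame(rng.normal(size=(500, 15)))
    assert pearson_greedy_filter(X, 0.9) == list(X.columns)


def test_pearson_postcondition_on_random_tables():
    rng = np.random.default_rng(8)
    for _ in range(50):
        base = rng.normal(size=(60, 4))
        mix = rng.normal(size=(4, 12))
        X = _frame(base @ mix + 0.3 * rng.normal(size=(60, 12)))
        survivors = pearson_greedy_filter(X, 0.8)
        if len(survivors) > 1:
            c = np.abs(np.corrcoef(X[survivors].to_numpy(), rowvar=False))
            np.fill_diagonal(c, 0)
            assert c.max() <= 0.8 + 1e-12


# --------------------------------------------------------------- mRMR

def test_mrmr_informative_feature_selected_first():
    rng = np.random.default_rng(9)
    y = rng.integers(0, 2, 300)
    X = _frame(rng.normal(size=(300, 6)))
    X["f3"] = y + 0.05 * rng.normal(size=300)  # essentially the label
    assert mrmr_select(X, y, 3)[0] == "f3"


def test_mrmr_redundancy_defers_duplicate():
    rng = np.random.default_rng(10)
    y = rng.integers(0, 2, 200)
    info = y + 0.3 * rng.normal(size=200)
    other = y + 0.5 * rng.normal(size=200)  # weaker but independent signal
    X = pd.DataFrame({
        "dup1": info, "dup2": info.copy(), "indep": other,
        "noise1": rng.normal(size=200), "noise2": rng.normal(size=200),
    })
    order = mrmr_select(X, y, 3)
    assert order[0] == "dup1"
    assert order[1] == "indep"  # dup2's redundancy penalty defers it


def test_mrmr_greedy_step_matches_exhaustive_oracle():
    rng = np.random.default_rng(11)
    y = rng.integers(0, 2, 150)
    X = _frame(rng.normal(size=(150, 8)))
    X["f0"] += 0.8 * y
    X["f1"] += 0.5 * y
    tertiles = {c: oracles.discretize_fbw(list(X[c]), width=np.ptp(X[c]) / 3) for c in X}
    # oracle uses equal-frequency tertiles like the implementation
    def tert(col):
        q = np.quantile(X[col], [1 / 3, 2 / 3])
        return list(np.searchsorted(q, X[col], side="right"))

    chosen = mrmr_select(X, y, 5)
    oracle_sel = []
    remaining = sorted(X.columns)
    for step in range(5):
        best, best_score = None, -np.inf
        for c in remaining:
            rel = oracles.oracle_mi(tert(c), list(y))
            red = (
                np.mean([oracles.oracle_mi(tert(c), tert(s)) for s in oracle_sel])
                if oracle_sel else 0.0
            )
            if rel - red > best_score + 1e-15:
                best, best_score = c, rel - red
        oracle_sel.append(best)
        remaining.remove(best)
        assert chosen[step] == best, f"greedy step {step}"


def test_mrmr_k_too_large_rejected():
    X = _frame(np.random.default_rng(0).normal(size=(30, 3)))
    with pytest.raises(ValueError, match="exceeds"):
        mrmr_select(X, np.r_[np.ones(15), np.zeros(15)], 4)


# --------------------------------------------------------------- Lasso

def test_l1_fit_tiny_penalty_recovers_unpenalized_logistic():
    import statsmodels.api as sm

    rng = np.random.default_rng(12)
    X = rng.normal(size=(400, 3))
    lin = 0.8 * X[:, 0] - 0.5 * X[:, 1]
    y = (rng.random(400) < 1 / (1 + np.exp(-lin))).astype(int)
    ref = sm.Logit(y, sm.add_constant(X)).fit(disp=0)
    m = l1_logistic_fit(X, y, lam=1e-8)
    assert np.allclose(m.coef_.ravel(), ref.params[1:], atol=1e-3)


def test_lasso_zeroes_noise_keeps_signal():
    rng = np.random.default_rng(13)
    kept_signal, zeroed_noise = 0, []
    for rep in range(20):
        X = _frame(rng.normal(size=(300, 21)))
        lin = 1.5 * X["f0"].to_numpy()
        y = (rng.random(300) < 1 / (1 + np.exp(-lin))).astype(int)
        survivors, coefs = lasso_select(X, y, seed=rep, rule="1se")
        kept_signal += "f0" in survivors
        zeroed_noise.append(np.mean([coefs[f"f{i}"] == 0 for i in range(1, 21)]))
    assert kept_signal == 20
    assert np.mean(zeroed_noise) >= 0.9


def test_lasso_all_zero_solution_reports_empty():
    rng = np.random.default_rng(14)
    X = _frame(rng.normal(size=(60, 5)))
    y = rng.integers(0, 2, 60)  # pure noise: heavy penalty wins
    survivors, coefs = lasso_select(X, y, seed=0, rule="1se")
    assert set(survivors) == set(coefs.index[coefs != 0.0])


# ------------------------------------------------------------- cascade

def test_cascade_survivors_nested_and_counts_non_increasing():
    rng = np.random.default_rng(15)
    y = np.r_[np.ones(60), np.zeros(60)].astype(int)
    X = _frame(rng.normal(size=(120, 25)))
    for j in range(4):
        X[f"f{j}"] += (0.8 + 0.3 * j) * y
    X["f20"] = X["f0"] + 0.01 * rng.normal(size=120)  # near-duplicate
    retest = X + 0.05 * rng.normal(size=X.shape)
    survivors, scaler, report = run_cascade(X, retest, y, mrmr_k=10, seed=0)
    order = report.stages
    assert order == ["icc", "ttest", "pearson", "mrmr", "lasso"]
    sets = [set(report.survivors[s]) for s in order]
    for earlier, later in zip(sets, sets[1:]):
        assert later <= earlier
    counts = [report.counts[s] for s in order]
    assert counts == sorted(counts, reverse=True)
    assert set(survivors) == sets[-1]
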