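"""The five-stage feature-selection cascade.

Order is fixed: ICC robustness filter -> z-score standardization +
Welch t-test filter -> greedy Pearson de-correlation -> mRMR -> Lasso.
Survivor sets are strictly nested and all statistics are computed on
training samples only; z-scoring parameters are stored for reuse on
held-out samples.

ICC is ICC(2,1): two-way random effects, absolute agreement, single
measurement. mRMR is the difference (MID) form with mutual information
estimated on equal-frequency tertiles. The Lasso stage is an
L1-penalized logistic regression with the penalty chosen by
cross-validated deviance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import mutual_info_score
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "SelectionReport",
    "Standardizer",
    "icc_2_1",
    "icc_filter",
    "standardize_and_ttest",
    "pearson_greedy_filter",
    "mrmr_select",
    "l1_logistic_fit",
    "lasso_select",
    "run_cascade",
]


@dataclass
class Standardizer:
    """Training-set z-score parameters, reusable on held-out samples."""

    mean: pd.Series
    std: pd.Series

    def transform(self, table: pd.DataFrame) -> pd.DataFrame:
        cols = self.mean.index
        return (table[cols] - self.mean) / self.std


@dataclass
class SelectionReport:
    """Per-stage survivors, counts and per-feature statistics."""

    stages: list[str] = field(default_factory=list)
    survivors: dict[str, list[str]] = field(default_factory=dict)
    counts: dict[str, int] = field(default_factory=dict)
    statistics: dict[str, dict[str, float]] = field(default_factory=dict)
    dropped_reasons: dict[str, str] = field(default_factory=dict)

    def record(self, stage: str, names: list[str], stats_: dict[str, float] | None = None) -> None:
        self.stages.append(stage)
        self.survivors[stage] = list(names)
        self.counts[stage] = len(names)
        if stats_:
            self.statistics[stage] = {k: float(v) for k, v in stats_.items()}

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {
                "stages": self.stages,
                "counts": self.counts,
                "survivors": self.survivors,
                "statistics": self.statistics,
                "dropped": self.dropped_reasons,
            },
            indent=2,
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload


# ------------------------------------------------------------------ ICC

def icc_2_1(a: np.ndarray, b: np.ndarray) -> float:
    """ICC(2,1): two-way random, absolute agreement, single measurement.

    ``a`` and ``b`` are the two measurements of the same n targets
    (here: a feature under original vs perturbed segmentation).
    """
    x = np.column_stack([np.asarray(a, float), np.asarray(b, float)])
    n, k = x.shape
    if n < 2:
        raise ValueError("need at least two targets for ICC")
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((x - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom == 0:
        return np.nan
    return float((msr - mse) / denom)


def icc_filter(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    threshold: float = 0.85,
    report: SelectionReport | None = None,
) -> list[str]:
    """Keep features whose test–retest ICC(2,1) meets ``threshold``.

    Zero-variance features have an undefined ICC and are dropped with a
    logged reason.
    """
    if list(table_a.columns) != list(table_b.columns) or not table_a.index.equals(table_b.index):
        table_b = table_b.loc[table_a.index, table_a.columns]
    survivors = []
    iccs: dict[str, float] = {}
    dropped: dict[str, str] = {}
    for col in table_a.columns:
        a = table_a[col].to_numpy()
        b = table_b[col].to_numpy()
        if np.std(a) == 0 and np.std(b) == 0:
            dropped[col] = "zero variance in both measurements; ICC undefined"
            continue
        icc = icc_2_1(a, b)
        iccs[col] = icc
        if np.isnan(icc):
            dropped[col] = "ICC undefined"
        elif icc >= threshold:
            survivors.append(col)
    if report is not None:
        report.record("icc", survivors, iccs)
        report.dropped_reasons.update(dropped)
    return survivors


# ------------------------------------------------- z-score + t-test

def standardize_and_ttest(
    table: pd.DataFrame,
    labels: np.ndarray,
    alpha: float = 0.05,
    report: SelectionReport | None = None,
) -> tuple[list[str], pd.DataFrame, Standardizer]:
    """Z-score on the training table and keep features with Welch p < alpha.

    Returns (survivors, z-scored table, fitted standardizer). A feature
    with zero pooled variance carries no signal: its p-value is set to
    1.0 by convention and logged.
    """
    labels = np.asarray(labels).astype(bool)
    if labels.all() or not labels.any():
        raise ValueError("both classes must be present")
    if min(labels.sum(), (~labels).sum()) < 3:
        raise ValueError("need at least 3 samples per class")
    mu = table.mean()
    sd = table.std(ddof=0).replace(0.0, 1.0)
    scaler = Standardizer(mu, sd)
    z = scaler.transform(table)

    pvals: dict[str, float] = {}
    for col in table.columns:
        x1 = table.loc[labels, col].to_numpy()
        x0 = table.loc[~labels, col].to_numpy()
        if x1.var() == 0 and x0.var() == 0:
            pvals[col] = 1.0
        else:
            pvals[col] = float(stats.ttest_ind(x1, x0, equal_var=False).pvalue)
    survivors = [c for c in table.columns if pvals[c] < alpha]
    if report is not None:
        report.record("ttest", survivors, pvals)
    return survivors, z, scaler


# ------------------------------------------- greedy Pearson filter

def pearson_greedy_filter(
    table: pd.DataFrame,
    r_threshold: float = 0.9,
    report: SelectionReport | None = None,
) -> list[str]:
    """Greedy recursive de-correlation.

    While some pair has |r| > threshold, delete — from the currently
    worst pair — the member with the larger mean |r| against all
    remaining features; ties break in feature-name order. The surviving
    set has max pairwise |r| <= threshold.
    """
    cols = list(table.columns)
    if len(cols) < 2:
        if report is not None:
            report.record("pearson", cols)
        return cols
    corr = np.abs(np.corrcoef(table.to_numpy(), rowvar=False))
    np.fill_diagonal(corr, 0.0)
    corr = np.nan_to_num(corr)
    alive = list(range(len(cols)))
    while True:
        sub = corr[np.ix_(alive, alive)]
        mx = sub.max() if len(alive) > 1 else 0.0
        if mx <= r_threshold:
            break
        i_, j_ = np.unravel_index(np.argmax(sub), sub.shape)
        a, b = alive[i_], alive[j_]
        # mean |r| vs all remaining features (excluding self)
        mean_a = sub[i_].sum() / (len(alive) - 1)
        mean_b = sub[j_].sum() / (len(alive) - 1)
        if mean_a > mean_b:
            drop = a
        elif mean_b > mean_a:
            drop = b
        else:  # tie: drop the later name
            drop = max(a, b, key=lambda k: cols[k])
        alive.remove(drop)
    survivors = [cols[i] for i in alive]
    if report is not None:
        report.record("pearson", survivors)
    return survivors


# ------------------------------------------------------------- mRMR

def _tertile_bins(x: np.ndarray) -> np.ndarray:
    qs = np.quantile(x, [1 / 3, 2 / 3])
    return np.searchsorted(qs, x, side="right")


def mrmr_select(
    table: pd.DataFrame,
    labels: np.ndarray,
    k: int,
    report: SelectionReport | None = None,
) -> list[str]:
    """Greedy mRMR (difference form): argmax I(f; y) - mean I(f; selected).

    Mutual information is estimated on equal-frequency tertiles of each
    feature. Ties break in feature-name order (pandas column order after
    a stable sort by criterion).
    """
    cols = list(table.columns)
    if k > len(cols):
        raise ValueError(f"k={k} exceeds the {len(cols)} available features")
    y = np.asarray(labels).astype(int)
    binned = {c: _tertile_bins(table[c].to_numpy()) for c in cols}
    relevance = {c: mutual_info_score(binned[c], y) for c in cols}

    selected: list[str] = []
    remaining = sorted(cols)
    pair_mi: dict[tuple[str, str], float] = {}

    def redundancy(c: str) -> float:
        if not selected:
            return 0.0
        tot = 0.0
        for s in selected:
            key = (min(c, s), max(c, s))
            if key not in pair_mi:
                pair_mi[key] = mutual_info_score(binned[c], binned[s])
            tot += pair_mi[key]
        return tot / len(selected)

    scores: dict[str, float] = {}
    for _ in range(k):
        best, best_score = None, -np.inf
        for c in remaining:  # name order => deterministic tie-break
            score = relevance[c] - redundancy(c)
            if score > best_score + 1e-15:
                best, best_score = c, score
        selected.append(best)
        scores[best] = best_score
        remaining.remove(best)
    if report is not None:
        report.record("mrmr", selected, scores)
    return selected


# ------------------------------------------------------------- Lasso

def l1_logistic_fit(X: np.ndarray, y: np.ndarray, lam: float) -> LogisticRegression:
    """L1-penalized logistic fit minimizing mean deviance + lam * ||beta||_1."""
    model = LogisticRegression(
        l1_ratio=1.0, C=1.0 / (lam * len(y)), solver="liblinear", max_iter=5000,
        tol=1e-8, random_state=0,
    )
    return model.fit(X, y)


def lasso_select(
    table: pd.DataFrame,
    labels: np.ndarray,
    cv_folds: int = 5,
    n_lambdas: int = 30,
    seed: int = 0,
    rule: str = "min",
    report: SelectionReport | None = None,
) -> tuple[list[str], pd.Series]:
    """L1-logistic selection with lambda chosen by cross-validated deviance.

    ``rule="min"`` takes the deviance-minimizing lambda; ``rule="1se"``
    the largest lambda within one standard error of the minimum
    (sparser). Returns (survivors, coefficients at the chosen lambda).
    If the chosen penalty zeroes every coefficient the survivor set is
    empty (reported, not an error).
    """
    if rule not in ("min", "1se"):
        raise ValueError("rule must be 'min' or '1se'")
    y = np.asarray(labels).astype(int)
    X = table.to_numpy()
    n = len(y)
    # lambda path down from the smallest penalty that zeroes everything
    lam_max = np.abs(X.T @ (y - y.mean())).max() / n
    lam_max = max(lam_max, 1e-6)
    lams = np.geomspace(lam_max, lam_max * 1e-3, n_lambdas)
    cv = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)

    mean_dev, se_dev = [], []
    for lam in lams:
        devs = []
        for tr, te in cv.split(X, y):
            m = l1_logistic_fit(X[tr], y[tr], lam)
            p = np.clip(m.predict_proba(X[te])[:, 1], 1e-12, 1 - 1e-12)
            devs.append(-2.0 * np.mean(y[te] * np.log(p) + (1 - y[te]) * np.log(1 - p)))
        mean_dev.append(np.mean(devs))
        se_dev.append(np.std(devs, ddof=1) / np.sqrt(len(devs)))
    i_min = int(np.argmin(mean_dev))
    if rule == "1se":
        cutoff = mean_dev[i_min] + se_dev[i_min]
        # lams descend, so the first index within the cutoff is the sparsest
        best_lam = lams[next(i for i in range(len(lams)) if mean_dev[i] <= cutoff)]
    else:
        best_lam = lams[i_min]
    final = l1_logistic_fit(X, y, best_lam)
    coefs = pd.Series(final.coef_.ravel(), index=table.columns)
    survivors = list(coefs.index[coefs != 0.0])
    if report is not None:
        report.record("lasso", survivors, dict(coefs[coefs != 0.0]))
        report.statistics["lasso_lambda"] = {"lambda": float(best_lam)}
    return survivors, coefs


# ---------------------------------------------------------- cascade

def run_cascade(
    table: pd.DataFrame,
    retest_table: pd.DataFrame | None,
    labels: np.ndarray,
    icc_threshold: float = 0.85,
    alpha: float = 0.05,
    r_threshold: float = 0.9,
    mrmr_k: int = 30,
    lasso_folds: int = 5,
    seed: int = 0,
) -> tuple[list[str], Standardizer, SelectionReport]:
    """Full cascade on a training table; returns survivors + scaler + report.

    ``retest_table`` carries the same features under a perturbed
    segmentation (ICC stage); pass None to skip the ICC stage (all
    features enter the t-test stage).
    """
    report = SelectionReport()
    if retest_table is not None:
        cols = icc_filter(table, retest_table, icc_threshold, report)
    else:
        cols = list(table.columns)
        report.record("icc", cols)
    if not cols:
        raise ValueError("no feature survived the ICC stage")

    survivors, z, scaler = standardize_and_ttest(table[cols], labels, alpha, report)
    if not survivors:
        return [], scaler, report
    survivors = pearson_greedy_filter(z[survivors], r_threshold, report)
    k = min(mrmr_k, len(survivors))
    survivors = mrmr_select(z[survivors], labels, k, report)
    survivors, _ = lasso_select(z[survivors], labels, lasso_folds, seed=seed, report=report)
    return survivors, scaler, report
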