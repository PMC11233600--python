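"""Evaluation statistics: ROC/AUC with DeLong CI, the paired DeLong test,
Hosmer–Lemeshow calibration, decision-curve analysis, and the cosine
learning-rate schedule.

AUC is the Mann–Whitney statistic (ties counted 1/2), identical to the
trapezoidal ROC area. Its variance and the paired test use DeLong's
structural components (per-sample placement values). Net benefit at a
probability threshold pt is TP/n - (FP/n) * pt / (1 - pt).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "EvaluationReport",
    "LRScheduleParams",
    "roc_auc",
    "auc_mann_whitney",
    "delong_test",
    "hosmer_lemeshow",
    "calibration_bins",
    "decision_curve",
    "operating_point",
    "cosine_lr",
    "evaluate_models",
]


# ------------------------------------------------------------- ROC/AUC

def _check_scores_labels(scores, labels):
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    if s.shape != y.shape:
        raise ValueError("scores and labels must align")
    if y.min() == y.max():
        raise ValueError("both classes must be present")
    return s, y


def auc_mann_whitney(scores, labels) -> float:
    """AUC as the normalized Mann–Whitney U (ties count 1/2)."""
    s, y = _check_scores_labels(scores, labels)
    ranks = stats.rankdata(s)
    n1 = int(y.sum())
    n0 = len(y) - n1
    u = ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def _placements(scores, labels):
    """DeLong structural components V10 (cases) and V01 (controls)."""
    s, y = _check_scores_labels(scores, labels)
    pos = s[y == 1]
    neg = s[y == 0]
    # placement of each case among controls and vice versa, ties 1/2
    v10 = np.array([(np.sum(p > neg) + 0.5 * np.sum(p == neg)) / len(neg) for p in pos])
    v01 = np.array([(np.sum(pos > n_) + 0.5 * np.sum(pos == n_)) / len(pos) for n_ in neg])
    return v10, v01


def roc_auc(scores, labels, alpha: float = 0.95) -> tuple[float, tuple[float, float]]:
    """AUC with a DeLong-variance Wald confidence interval (clipped to [0, 1])."""
    v10, v01 = _placements(scores, labels)
    auc = float(v10.mean())
    var = v10.var(ddof=1) / len(v10) + v01.var(ddof=1) / len(v01)
    z = stats.norm.ppf(0.5 + alpha / 2.0)
    half = z * np.sqrt(max(var, 0.0))
    return auc, (max(0.0, auc - half), min(1.0, auc + half))


def delong_test(scores_a, scores_b, labels) -> tuple[float, float]:
    """Paired DeLong test for the difference of two correlated AUCs.

    Returns (z, two-sided p). Scores must be paired on identical samples.
    """
    sa = np.asarray(scores_a, dtype=float)
    sb = np.asarray(scores_b, dtype=float)
    if sa.shape != sb.shape:
        raise ValueError("paired scores must have identical shape")
    va10, va01 = _placements(sa, labels)
    vb10, vb01 = _placements(sb, labels)
    auc_a, auc_b = va10.mean(), vb10.mean()
    m, n = len(va10), len(va01)
    s10 = np.cov(np.stack([va10, vb10]), ddof=1)
    s01 = np.cov(np.stack([va01, vb01]), ddof=1)
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    diff = auc_a - auc_b
    if var <= 0:
        if abs(diff) < 1e-12:
            return 0.0, 1.0
        raise ValueError("zero variance of the AUC difference with unequal AUCs")
    z = diff / np.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)


# -------------------------------------------------------- calibration

def hosmer_lemeshow(probs, labels, g: int = 10) -> tuple[float, int, float]:
    """Hosmer–Lemeshow chi-square over deciles of risk.

    chi2 = sum (O - E)^2 / (E (1 - E/n_g)); df = #groups - 2. Empty or
    degenerate groups (quantile ties) are merged with their neighbor and
    the df adjusted.
    """
    p = np.asarray(probs, dtype=float)
    y = np.asarray(labels).astype(int)
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("probabilities must lie strictly in (0, 1)")
    if len(p) < g:
        raise ValueError(f"need at least g={g} samples")
    edges = np.unique(np.quantile(p, np.linspace(0, 1, g + 1)))
    groups = np.clip(np.searchsorted(edges, p, side="right") - 1, 0, len(edges) - 2)
    chi2 = 0.0
    n_groups = 0
    for gi in np.unique(groups):
        sel = groups == gi
        ng = sel.sum()
        e = p[sel].sum()
        o = y[sel].sum()
        denom = e * (1.0 - e / ng)
        if denom <= 0:
            continue
        chi2 += (o - e) ** 2 / denom
        n_groups += 1
    df = max(n_groups - 2, 1)
    return float(chi2), int(df), float(stats.chi2.sf(chi2, df))


def calibration_bins(probs, labels, g: int = 10) -> pd.DataFrame:
    """Mean predicted vs observed event rate per risk decile."""
    p = np.asarray(probs, dtype=float)
    y = np.asarray(labels).astype(int)
    edges = np.unique(np.quantile(p, np.linspace(0, 1, g + 1)))
    groups = np.clip(np.searchsorted(edges, p, side="right") - 1, 0, len(edges) - 2)
    rows = []
    for gi in np.unique(groups):
        sel = groups == gi
        rows.append({"n": int(sel.sum()), "mean_predicted": float(p[sel].mean()),
                     "observed": float(y[sel].mean())})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------- DCA

def decision_curve(
    probs_by_model: dict[str, np.ndarray],
    labels,
    thresholds: np.ndarray | None = None,
) -> pd.DataFrame:
    """Net benefit per model plus treat-all / treat-none references.

    NB(pt) = TP/n - (FP/n) * pt/(1-pt); treat-all: pi - (1-pi)*pt/(1-pt);
    treat-none: 0. Default threshold grid 0.01..0.99 step 0.01.
    """
    y = np.asarray(labels).astype(int)
    n = len(y)
    pi = y.mean()
    if thresholds is None:
        thresholds = np.arange(0.01, 1.0, 0.01)
    thresholds = np.asarray(thresholds, dtype=float)
    if np.any((thresholds <= 0) | (thresholds >= 1)):
        raise ValueError("thresholds must lie strictly in (0, 1)")
    out = {"threshold": thresholds,
           "treat_all": pi - (1 - pi) * thresholds / (1 - thresholds),
           "treat_none": np.zeros_like(thresholds)}
    for name, probs in probs_by_model.items():
        p = np.asarray(probs, dtype=float)
        nb = np.empty_like(thresholds)
        for i, pt in enumerate(thresholds):
            pred = p >= pt
            tp = np.sum(pred & (y == 1))
            fp = np.sum(pred & (y == 0))
            nb[i] = tp / n - (fp / n) * pt / (1 - pt)
        out[name] = nb
    return pd.DataFrame(out)


# ----------------------------------------------------- operating point

def operating_point(scores, labels, threshold: float | None = None) -> dict[str, float]:
    """Accuracy/sensitivity/specificity/PPV/NPV at a threshold.

    With ``threshold=None`` the Youden-optimal point (max sens + spec - 1)
    on these scores is used — freeze the training threshold for held-out
    data by passing it explicitly.
    """
    s, y = _check_scores_labels(scores, labels)
    if threshold is None:
        cand = np.unique(s)
        best, threshold = -np.inf, cand[0]
        for t in cand:
            pred = s >= t
            sens = np.sum(pred & (y == 1)) / np.sum(y == 1)
            spec = np.sum(~pred & (y == 0)) / np.sum(y == 0)
            if sens + spec - 1 > best:
                best, threshold = sens + spec - 1, t
    pred = s >= threshold
    tp = int(np.sum(pred & (y == 1)))
    tn = int(np.sum(~pred & (y == 0)))
    fp = int(np.sum(pred & (y == 0)))
    fn = int(np.sum(~pred & (y == 1)))
    return {
        "threshold": float(threshold),
        "accuracy": (tp + tn) / len(y),
        "sensitivity": tp / (tp + fn) if tp + fn else 0.0,
        "specificity": tn / (tn + fp) if tn + fp else 0.0,
        "ppv": tp / (tp + fp) if tp + fp else 0.0,
        "npv": tn / (tn + fn) if tn + fn else 0.0,
    }


# -------------------------------------------------- LR schedule

@dataclass(frozen=True)
class LRScheduleParams:
    """Cosine-decay learning-rate schedule parameters."""

    eta_min: float = 0.0
    eta_max: float = 0.01
    T_i: int = 100
    T_cur: float = 0.0
    mode: str = "task_specific"  # or "backbone"

    def validate(self):
        if not (0 <= self.eta_min <= self.eta_max):
            raise ValueError("need 0 <= eta_min <= eta_max")
        if self.T_i <= 0:
            raise ValueError("T_i must be positive")
        if not (0 <= self.T_cur <= self.T_i):
            raise ValueError("need 0 <= T_cur <= T_i")
        if self.mode not in ("task_specific", "backbone"):
            raise ValueError(f"unknown mode {self.mode!r}")


def cosine_lr(params: LRScheduleParams) -> float:
    """Cosine-decay learning rate.

    task_specific: eta_min + (eta_max - eta_min)(1 + cos(pi T_cur/T_i))/2.
    backbone: 0 while T_cur <= T_i/2 (frozen pretrained layers), then the
    same cosine value.
    """
    params.validate()
    if params.mode == "backbone" and params.T_cur <= params.T_i / 2:
        return 0.0
    return params.eta_min + 0.5 * (params.eta_max - params.eta_min) * (
        1.0 + np.cos(np.pi * params.T_cur / params.T_i)
    )


# ----------------------------------------------------------- report

@dataclass
class EvaluationReport:
    """Bundle of per-model evaluation results on one partition."""

    auc: dict[str, float] = field(default_factory=dict)
    auc_ci: dict[str, tuple[float, float]] = field(default_factory=dict)
    metrics: dict[str, dict[str, float]] = field(default_factory=dict)
    delong: pd.DataFrame | None = None
    hl: dict[str, tuple[float, int, float]] = field(default_factory=dict)
    calibration: dict[str, pd.DataFrame] = field(default_factory=dict)
    dca: pd.DataFrame | None = None

    def to_dict(self) -> dict:
        return {
            "auc": self.auc,
            "auc_ci": {k: list(v) for k, v in self.auc_ci.items()},
            "metrics": self.metrics,
            "delong_p": self.delong.to_dict() if self.delong is not None else None,
            "hosmer_lemeshow": {k: {"chi2": v[0], "df": v[1], "p": v[2]}
                                for k, v in self.hl.items()},
        }


def evaluate_models(
    scores_by_model: dict[str, np.ndarray],
    labels,
    thresholds: dict[str, float] | None = None,
) -> EvaluationReport:
    """Full evaluation of several score columns on one partition.

    ``thresholds`` maps model name -> frozen operating threshold (e.g.
    Youden point from training); missing entries are derived on the spot.
    """
    rep = EvaluationReport()
    names = list(scores_by_model)
    for name in names:
        s = scores_by_model[name]
        a, ci = roc_auc(s, labels)
        rep.auc[name] = a
        rep.auc_ci[name] = ci
        t = (thresholds or {}).get(name)
        rep.metrics[name] = operating_point(s, labels, t)
        probs = np.clip(np.asarray(s, float), 1e-9, 1 - 1e-9)
        rep.hl[name] = hosmer_lemeshow(probs, labels, g=min(10, len(probs) // 2))
        rep.calibration[name] = calibration_bins(probs, labels)
    pmat = pd.DataFrame(np.ones((len(names), len(names))), index=names, columns=names)
    for i, a_ in enumerate(names):
        for j in range(i + 1, len(names)):
            b_ = names[j]
            try:
                _, p = delong_test(scores_by_model[a_], scores_by_model[b_], labels)
            except ValueError:
                p = np.nan
            pmat.loc[a_, b_] = pmat.loc[b_, a_] = p
    rep.delong = pmat
    rep.dca = decision_curve(
        {k: np.asarray(v, float) for k, v in scores_by_model.items()}, labels
    )
    return rep
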