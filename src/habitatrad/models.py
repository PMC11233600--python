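"""Signature models, clinical analysis, and the fusion nomogram.

A *signature* is a per-region classifier score in [0, 1], trained with
stratified fivefold cross-validation and a grid search over a small
hyperparameter grid (MLP, random forest, SVM, logistic regression,
XGBoost, LightGBM, Extra-Trees). Clinical covariates get univariable and
stepwise multivariable logistic analyses. The nomogram is a logistic
fusion of signature scores plus smoking, re-encoded on a 0-100 point
scale that round-trips exactly to the fitted probability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit
from sklearn.ensemble import ExtraTreesClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

from .synthetic import CT_PATTERNS, GENDERS, HISTOLOGIES, LOBES, STAGES

__all__ = [
    "ALGORITHMS",
    "SignatureModel",
    "ClinicalAnalysis",
    "NomogramModel",
    "train_signature",
    "clinical_analysis",
    "encode_clinical",
    "build_nomogram",
    "dtl_placeholder_signature",
]


def _default_grids(seed: int) -> dict[str, tuple[object, dict]]:
    import lightgbm as lgb
    import xgboost as xgb

    return {
        "mlp": (
            MLPClassifier(max_iter=2000, random_state=seed),
            {"hidden_layer_sizes": [(16,), (32,)], "alpha": [1e-3, 1e-1]},
        ),
        "rf": (
            RandomForestClassifier(n_estimators=200, random_state=seed),
            {"max_depth": [3, None]},
        ),
        "svm": (
            SVC(probability=True, random_state=seed),
            {"C": [0.5, 2.0], "gamma": ["scale"]},
        ),
        "lr": (
            LogisticRegression(max_iter=5000),
            {"C": [0.1, 1.0, 10.0]},
        ),
        "xgboost": (
            xgb.XGBClassifier(n_estimators=150, verbosity=0, eval_metric="logloss",
                              random_state=seed),
            {"max_depth": [2, 3], "learning_rate": [0.1, 0.3]},
        ),
        "lightgbm": (
            lgb.LGBMClassifier(n_estimators=150, verbose=-1, random_state=seed),
            {"num_leaves": [7, 15]},
        ),
        "extratrees": (
            ExtraTreesClassifier(n_estimators=200, random_state=seed),
            {"max_depth": [3, None]},
        ),
    }


ALGORITHMS = ("mlp", "rf", "svm", "lr", "xgboost", "lightgbm", "extratrees")


@dataclass
class SignatureModel:
    """A fitted per-region signature: classifier + provenance."""

    region_tag: str
    algorithm: str
    estimator: object
    best_params: dict
    cv_auc: float
    feature_names: list[str]
    seed: int

    def scores(self, table: pd.DataFrame) -> np.ndarray:
        """Per-sample signature score in [0, 1]."""
        p = self.estimator.predict_proba(table[self.feature_names].to_numpy())[:, 1]
        return np.clip(p, 0.0, 1.0)


def train_signature(
    table: pd.DataFrame,
    labels: np.ndarray,
    algorithm: str = "svm",
    grid: dict | None = None,
    seed: int = 0,
    cv_folds: int = 5,
    region_tag: str = "",
) -> SignatureModel:
    """Grid-search a classifier by mean CV AUC and refit on all samples.

    Folds are stratified with a fixed seed. If the rarer class has fewer
    members than ``cv_folds`` the fold count is reduced (at least 2) so
    every fold sees both classes; with fewer than 2 per class this fails
    loudly.
    """
    if algorithm not in ALGORITHMS:
        raise ValueError(f"unknown algorithm {algorithm!r}; choose from {ALGORITHMS}")
    y = np.asarray(labels).astype(int)
    n_min = min((y == 1).sum(), (y == 0).sum())
    if n_min < 2:
        raise ValueError("need at least 2 samples of each class for stratified CV")
    folds = min(cv_folds, n_min)
    est, default_grid = _default_grids(seed)[algorithm]
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    search = GridSearchCV(est, grid or default_grid, scoring="roc_auc", cv=cv, n_jobs=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        search.fit(table.to_numpy(), y)
    return SignatureModel(
        region_tag=region_tag,
        algorithm=algorithm,
        estimator=search.best_estimator_,
        best_params=dict(search.best_params_),
        cv_auc=float(search.best_score_),
        feature_names=list(table.columns),
        seed=seed,
    )


# ------------------------------------------------------------ clinical

_CATEGORY_ORDERS = {
    "gender": GENDERS,
    "stage": STAGES,
    "smoking": ("no", "yes"),
    "ct_pattern": CT_PATTERNS,
    "histology": HISTOLOGIES,
    "location": LOBES,
}


def encode_clinical(clinical: pd.DataFrame) -> pd.DataFrame:
    """Numeric encoding: age as-is, categoricals as integer codes in the
    declared category order (one column, one OR per covariate)."""
    out = pd.DataFrame(index=clinical.index)
    out["age"] = clinical["age"].astype(float)
    for col, order in _CATEGORY_ORDERS.items():
        out[col] = clinical[col].map({v: i for i, v in enumerate(order)}).astype(float)
    return out


@dataclass
class ClinicalAnalysis:
    """Univariable and stepwise multivariable logistic results."""

    univariable: pd.DataFrame  # index covariate; OR, ci_low, ci_high, p
    multivariable: pd.DataFrame
    penalized: list[str] = field(default_factory=list)


def _logit_fit(X: pd.DataFrame, y: np.ndarray, penalized: list[str]):
    Xc = sm.add_constant(X, has_constant="add")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, Xc).fit(disp=0, maxiter=200)
        if not np.all(np.isfinite(res.bse)) or np.any(res.bse > 1e3):
            raise RuntimeError("separation")
        return res, False
    except Exception:
        penalized.extend(c for c in X.columns if c not in penalized)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, Xc).fit_regularized(alpha=1.0, L1_wt=0.0, disp=0)
        return res, True


def _or_table(res, cols, flagged: bool) -> pd.DataFrame:
    params = res.params
    rows = {}
    for c in cols:
        beta = params[c]
        if flagged or not hasattr(res, "bse"):
            lo = hi = p = np.nan
        else:
            se = res.bse[c]
            lo, hi = np.exp(beta - 1.96 * se), np.exp(beta + 1.96 * se)
            p = res.pvalues[c]
        rows[c] = {"OR": float(np.exp(beta)), "ci_low": float(lo), "ci_high": float(hi),
                   "p": float(p)}
    return pd.DataFrame(rows).T


def clinical_analysis(clinical: pd.DataFrame, labels: np.ndarray,
                      p_enter: float = 0.05, p_remove: float = 0.10) -> ClinicalAnalysis:
    """Univariable logistic OR per covariate + stepwise multivariable model.

    Stepwise: forward entry at p < ``p_enter``, backward removal at
    p > ``p_remove``, iterated to a fixed point. Separation triggers an
    L2-penalized fallback, flagged in ``penalized`` (no CI reported).
    """
    y = np.asarray(labels).astype(int)
    if len(y) < 20:
        raise ValueError("need at least 20 samples for clinical analysis")
    if y.all() or not y.any():
        raise ValueError("both classes required (single-class cohort)")
    X = encode_clinical(clinical) if clinical.dtypes.eq(object).any() else clinical.copy()

    penalized: list[str] = []
    uni = {}
    for col in X.columns:
        res, flagged = _logit_fit(X[[col]], y, penalized)
        uni[col] = _or_table(res, [col], flagged).loc[col]
    uni = pd.DataFrame(uni).T

    included: list[str] = []
    while True:
        changed = False
        # forward step: best p among candidates
        candidates = [c for c in X.columns if c not in included]
        best, best_p = None, 1.0
        for c in candidates:
            res, flagged = _logit_fit(X[included + [c]], y, penalized)
            p = np.nan if flagged else float(res.pvalues[c])
            if np.isfinite(p) and p < best_p:
                best, best_p = c, p
        if best is not None and best_p < p_enter:
            included.append(best)
            changed = True
        # backward step
        if included:
            res, flagged = _logit_fit(X[included], y, penalized)
            if not flagged:
                pv = res.pvalues[included]
                worst = pv.idxmax()
                if pv[worst] > p_remove:
                    included.remove(worst)
                    changed = True
        if not changed:
            break

    if included:
        res, flagged = _logit_fit(X[included], y, penalized)
        multi = _or_table(res, included, flagged)
    else:
        multi = pd.DataFrame(columns=["OR", "ci_low", "ci_high", "p"])
    return ClinicalAnalysis(uni, multi, penalized)


# ------------------------------------------------------------ nomogram

@dataclass
class NomogramModel:
    """Logistic fusion of signatures (+ smoking) with a points re-encoding.

    Per-predictor points are an affine re-encoding of the linear
    predictor: the reference value of each predictor (its observed min
    for positive coefficients, max for negative) maps to 0 points, and
    the predictor with the widest coefficient x range spans 100 points.
    Total points convert back to the fitted probability exactly.
    """

    predictors: list[str]
    coef: pd.Series
    intercept: float
    ref: pd.Series
    scale: float  # points per unit of linear predictor
    ridge_fallback: bool = False

    def linear_predictor(self, X: pd.DataFrame) -> np.ndarray:
        return self.intercept + X[self.predictors].to_numpy() @ self.coef.to_numpy()

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        return expit(self.linear_predictor(X))

    def points(self, X: pd.DataFrame) -> pd.DataFrame:
        pts = {
            c: self.scale * self.coef[c] * (X[c].to_numpy() - self.ref[c])
            for c in self.predictors
        }
        return pd.DataFrame(pts, index=X.index)

    def probability_from_points(self, total_points: np.ndarray) -> np.ndarray:
        base = self.intercept + float((self.coef * self.ref).sum())
        return expit(base + np.asarray(total_points) / self.scale)


def build_nomogram(
    signature_scores: pd.DataFrame,
    smoking: np.ndarray | None,
    labels: np.ndarray,
) -> NomogramModel:
    """Fit the fusion logistic on training data and build the point scale.

    ``signature_scores`` holds one column per signature (e.g. P3, habitat,
    DTL); ``smoking`` is an optional 0/1 vector appended as a predictor.
    Constant predictors are excluded from the fit (they cannot move the
    probability); near-collinear designs fall back to a ridge fit with a
    warning and ``ridge_fallback=True``.
    """
    X = signature_scores.copy()
    if smoking is not None:
        X["smoking"] = np.asarray(smoking, dtype=float)
    y = np.asarray(labels).astype(int)

    rng_ = X.max() - X.min()
    constant = list(X.columns[rng_ == 0.0])
    if constant:
        warnings.warn(f"constant predictor(s) {constant} excluded from the nomogram fit",
                      stacklevel=2)
    keep = [c for c in X.columns if c not in constant]
    Xk = X[keep]

    ridge = False
    corr = np.corrcoef(Xk.to_numpy(), rowvar=False) if len(keep) > 1 else np.eye(1)
    if len(keep) > 1 and np.any(np.abs(corr[np.triu_indices(len(keep), 1)]) > 0.999):
        warnings.warn("collinear signatures: ridge fallback used", stacklevel=2)
        ridge = True
    Xc = sm.add_constant(Xk, has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if ridge:
            res = sm.Logit(y, Xc).fit_regularized(alpha=1.0, L1_wt=0.0, disp=0)
        else:
            try:
                res = sm.Logit(y, Xc).fit(disp=0, maxiter=500)
            except Exception:
                ridge = True
                res = sm.Logit(y, Xc).fit_regularized(alpha=1.0, L1_wt=0.0, disp=0)

    coef = pd.Series({c: float(res.params[c]) for c in keep})
    intercept = float(res.params["const"])
    ref = pd.Series({c: float(Xk[c].min() if coef[c] >= 0 else Xk[c].max()) for c in keep})
    spans = {c: abs(coef[c]) * (Xk[c].max() - Xk[c].min()) for c in keep}
    max_span = max(spans.values()) if spans else 1.0
    scale = 100.0 / max_span if max_span > 0 else 1.0
    return NomogramModel(keep, coef, intercept, ref, scale, ridge)


# ------------------------------------------- DTL placeholder signature

def dtl_placeholder_signature(
    volumes: list,
    labels: np.ndarray,
    train_idx: np.ndarray,
    seed: int = 0,
) -> np.ndarray:
    """Pluggable stand-in for a deep-transfer-learning score column.

    Summarizes the maximum-area axial tumor slice of each volume with
    simple intensity statistics and fits a logistic model on the training
    subset; returns a score in [0, 1] for every sample. Any per-sample
    score column can replace it in the nomogram.
    """
    rows = []
    for vol in volumes:
        areas = vol.mask.sum(axis=(0, 1))
        z = int(np.argmax(areas))
        vals = vol.intensities[:, :, z][vol.mask[:, :, z]]
        if vals.size == 0:
            vals = vol.intensities[vol.mask]
        rows.append([
            vals.mean(), vals.std(), np.percentile(vals, 10), np.percentile(vals, 90),
            float(vals.size),
        ])
    X = np.asarray(rows)
    mu, sd = X[train_idx].mean(axis=0), X[train_idx].std(axis=0)
    sd[sd == 0] = 1.0
    Xz = (X - mu) / sd
    model = LogisticRegression(max_iter=2000, random_state=seed)
    model.fit(Xz[train_idx], np.asarray(labels).astype(int)[train_idx])
    return model.predict_proba(Xz)[:, 1]
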