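"""Cross-validated sparse logistic prediction of antibody response.

A nested, stratified cross-validation scheme around L1-penalized
logistic regression: outer folds produce honest held-out response
probabilities for every sample, inner folds select the penalty by
mean held-out deviance, and the final reported model is refit on all
data at the median of the outer-fold penalties.  Features are
z-scored inside each training fold only, so no information from a
held-out sample leaks into its own prediction.

Penalty convention: lambda multiplies the L1 norm of the coefficients
in the average-log-likelihood objective, i.e. larger lambda means a
sparser model; lambda_max (all coefficients zero) is computed from the
gradient of the null model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import log_loss
from sklearn.model_selection import StratifiedKFold

from .data import ExpressionMatrix


def _lambda_grid(X: np.ndarray, y: np.ndarray, n_lambdas: int,
                 min_ratio: float) -> np.ndarray:
    n = len(y)
    p0 = y.mean()
    lam_max = np.abs(X.T @ (y - p0)).max() / n
    lam_max = max(lam_max, 1e-6)
    return np.geomspace(lam_max, lam_max * min_ratio, n_lambdas)


class _SparseLogit:
    """L1 logistic fit with an unpenalized intercept.

    Coefficients come from liblinear; the intercept is then refit by a
    one-dimensional Newton step so it is not shrunk by the penalty
    (liblinear penalizes its intercept term), which matters in the
    near-intercept-only regime where the held-out probability should
    equal the training prevalence.
    """

    def __init__(self, coef: np.ndarray, intercept: float):
        self.coef_ = coef.reshape(1, -1)
        self.intercept_ = np.array([intercept])

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        z = X @ self.coef_[0] + self.intercept_[0]
        p1 = 1.0 / (1.0 + np.exp(-z))
        return np.column_stack([1.0 - p1, p1])


def _fit_l1_logistic(X: np.ndarray, y: np.ndarray, lam: float) -> _SparseLogit:
    # liblinear solves C * sum(logloss) + |w|_1; lambda on the mean scale
    C = 1.0 / (lam * len(y))
    model = LogisticRegression(
        l1_ratio=1, C=C, solver="liblinear", tol=1e-7, max_iter=2000,
        intercept_scaling=50.0, random_state=0,
    )
    model.fit(X, y)
    w = model.coef_[0]
    b = float(model.intercept_[0])
    z_fixed = X @ w
    for _ in range(50):  # Newton on the intercept alone
        p = 1.0 / (1.0 + np.exp(-(z_fixed + b)))
        grad = p.mean() - y.mean()
        hess = max((p * (1.0 - p)).mean(), 1e-12)
        step = grad / hess
        b -= step
        if abs(step) < 1e-10:
            break
    return _SparseLogit(w, b)


class NestedLassoLogisticCV(BaseEstimator, ClassifierMixin):
    """Nested-CV L1 logistic classifier with honest held-out probabilities.

    Fitted attributes
    -----------------
    heldout_proba_ : ndarray
        Per-sample probability from the outer fold that excluded it.
    lambda_ : float
        Median of the outer-fold selected penalties; used for the final
        refit on all data.
    selected_features_ : list
        Feature names with nonzero coefficient in the final model.
    """

    def __init__(self, k_folds: int = 5, inner_folds: int = 5,
                 n_lambdas: int = 50, lambda_min_ratio: float = 1e-3,
                 standardize: str = "fold", random_state: int = 0):
        self.k_folds = k_folds
        self.inner_folds = inner_folds
        self.n_lambdas = n_lambdas
        self.lambda_min_ratio = lambda_min_ratio
        self.standardize = standardize  # "fold" (honest) or "global" (diagnostic)
        self.random_state = random_state

    @staticmethod
    def _scale_params(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        mu = X.mean(axis=0)
        sd = X.std(axis=0, ddof=0)
        sd = np.where(sd > 0, sd, 1.0)
        return mu, sd

    def fit(self, X, y):
        X = pd.DataFrame(X)
        self.feature_names_ = list(X.columns)
        Xm = X.to_numpy(dtype=float)
        y = np.asarray(y)
        classes = np.unique(y)
        if len(classes) != 2:
            raise ValueError(f"need exactly two classes, got {classes}")
        yb = (y == classes[1]).astype(int)
        self.classes_ = classes
        if min(yb.sum(), len(yb) - yb.sum()) < self.k_folds:
            raise ValueError(
                "too few samples in the minority class for stratified "
                f"{self.k_folds}-fold CV"
            )

        global_mu, global_sd = self._scale_params(Xm)
        outer = StratifiedKFold(
            n_splits=self.k_folds, shuffle=True, random_state=self.random_state
        )
        heldout = np.full(len(yb), np.nan)
        fold_of = np.full(len(yb), -1, dtype=int)
        lambdas = []
        for f, (tr, te) in enumerate(outer.split(Xm, yb)):
            if self.standardize == "global":
                mu, sd = global_mu, global_sd
            else:
                mu, sd = self._scale_params(Xm[tr])
            Xtr = (Xm[tr] - mu) / sd
            Xte = (Xm[te] - mu) / sd
            ytr = yb[tr]
            grid = _lambda_grid(Xtr, ytr, self.n_lambdas, self.lambda_min_ratio)
            lam = self._select_lambda(Xtr, ytr, grid, seed=self.random_state + 1 + f)
            lambdas.append(lam)
            model = _fit_l1_logistic(Xtr, ytr, lam)
            heldout[te] = model.predict_proba(Xte)[:, 1]
            fold_of[te] = f

        self.lambda_per_fold_ = np.array(lambdas)
        self.lambda_ = float(np.median(lambdas))
        self.fold_assignments_ = fold_of
        self.heldout_proba_ = heldout

        self.scale_mu_, self.scale_sd_ = global_mu, global_sd
        Xs = (Xm - global_mu) / global_sd
        final = _fit_l1_logistic(Xs, yb, self.lambda_)
        self.coef_ = final.coef_[0]
        self.intercept_ = float(final.intercept_[0])
        self.selected_features_ = [
            name for name, c in zip(self.feature_names_, self.coef_) if c != 0.0
        ]
        return self

    def _select_lambda(self, X: np.ndarray, y: np.ndarray, grid: np.ndarray,
                       seed: int) -> float:
        inner = StratifiedKFold(n_splits=self.inner_folds, shuffle=True,
                                random_state=seed)
        deviance = np.zeros(len(grid))
        for tr, te in inner.split(X, y):
            mu, sd = self._scale_params(X[tr])
            Xtr = (X[tr] - mu) / sd
            Xte = (X[te] - mu) / sd
            for i, lam in enumerate(grid):
                model = _fit_l1_logistic(Xtr, y[tr], lam)
                prob = model.predict_proba(Xte)[:, 1]
                deviance[i] += log_loss(y[te], prob, labels=[0, 1])
        return float(grid[int(np.argmin(deviance))])

    def predict_proba(self, X) -> np.ndarray:
        X = pd.DataFrame(X)
        Xs = (X.to_numpy(dtype=float) - self.scale_mu_) / self.scale_sd_
        logits = Xs @ self.coef_ + self.intercept_
        p1 = 1.0 / (1.0 + np.exp(-logits))
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X) -> np.ndarray:
        p = self.predict_proba(X)[:, 1]
        return self.classes_[(p >= 0.5).astype(int)]


@dataclass
class PredictionModel:
    """Sparse logistic model plus its honest held-out probabilities."""

    selected_features: list[str]
    coefficients: pd.Series           # includes "intercept"
    lambda_: float
    fold_assignments: pd.Series
    heldout_probabilities: pd.Series
    labels: pd.Series                 # 1 = responder
    estimator: NestedLassoLogisticCV


def lasso_logistic_cv(
    expr_week2: ExpressionMatrix | pd.DataFrame,
    labels: pd.Series,
    k_folds: int = 5,
    inner_folds: int = 5,
    n_lambdas: int = 50,
    seed: int = 0,
) -> PredictionModel:
    """Nested-CV LASSO on week-2 samples (columns) given 0/1 labels."""
    if isinstance(expr_week2, ExpressionMatrix):
        values = expr_week2.values
    else:
        values = expr_week2
    labels = pd.Series(labels)
    X = values.T.loc[labels.index]       # samples x genes
    est = NestedLassoLogisticCV(
        k_folds=k_folds, inner_folds=inner_folds, n_lambdas=n_lambdas,
        random_state=seed,
    )
    est.fit(X, labels.to_numpy())
    coef = pd.Series(est.coef_, index=est.feature_names_)
    coef["intercept"] = est.intercept_
    return PredictionModel(
        selected_features=est.selected_features_,
        coefficients=coef,
        lambda_=est.lambda_,
        fold_assignments=pd.Series(est.fold_assignments_, index=X.index),
        heldout_probabilities=pd.Series(est.heldout_proba_, index=X.index),
        labels=labels,
        estimator=est,
    )


@dataclass
class RocSummary:
    auroc: float
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    confusion: dict


def roc_auc(probabilities, labels, threshold: float = 0.5) -> RocSummary:
    """AUROC via the Mann-Whitney rank formulation; ties count 1/2."""
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels).astype(int)
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(p)
    auroc = (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    thresholds = np.unique(np.concatenate([[0.0], np.unique(p), [1.0]]))
    sens = np.array([(p[y == 1] >= t).mean() for t in thresholds])
    spec = np.array([(p[y == 0] < t).mean() for t in thresholds])
    return RocSummary(
        auroc=float(auroc),
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spec,
        confusion=confusion_at_threshold(p, y, threshold),
    )


def confusion_at_threshold(probabilities, labels, threshold: float = 0.5) -> dict:
    """Confusion counts and percent sensitivity/specificity (one decimal).

    A sample is predicted positive iff its probability >= threshold.
    """
    p = np.asarray(probabilities, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("probabilities must lie in [0, 1]")
    y = np.asarray(labels).astype(int)
    pred = (p >= threshold).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    sens = 100.0 * tp / (tp + fn) if tp + fn else float("nan")
    spec = 100.0 * tn / (tn + fp) if tn + fp else float("nan")
    return {
        "tp": tp, "fn": fn, "tn": tn, "fp": fp,
        "sensitivity": round(sens, 1),
        "specificity": round(spec, 1),
    }


def odds_titer_correlation(
    probabilities,
    titers_week12,
    titer_ratio,
    log_titer: bool = True,
    clip: float = 10.0,
) -> dict:
    """Regress predicted log-odds on (log) titer and (log) titer ratio.

    Returns R^2 and the slope t-test p-value for both regressions.
    Probabilities are converted to log-odds and clipped at +/- ``clip``.
    """
    p = np.asarray(probabilities, dtype=float)
    if np.any((p <= 0) | (p >= 1)):
        warnings.warn("probabilities at 0 or 1: log-odds clipped")
    p = np.clip(p, 1e-12, 1 - 1e-12)
    odds = np.clip(np.log(p / (1 - p)), -clip, clip)
    titers = np.asarray(titers_week12, dtype=float)
    ratio = np.asarray(titer_ratio, dtype=float)
    if np.any(titers <= 0) or np.any(ratio <= 0):
        raise ValueError("titers and ratios must be positive")
    x_t = np.log(titers) if log_titer else titers
    x_r = np.log(ratio) if log_titer else ratio
    fit_t = stats.linregress(x_t, odds)
    fit_r = stats.linregress(x_r, odds)
    return {
        "r2_titer": float(fit_t.rvalue**2),
        "p_titer": float(fit_t.pvalue),
        "r2_ratio": float(fit_r.rvalue**2),
        "p_ratio": float(fit_r.pvalue),
    }
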