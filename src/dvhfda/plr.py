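"""Penalized (LASSO) logistic regression comparator on sampled DVH points.

The non-functional baseline: the DVH is sampled at 13 fractional-dose
levels (0.2 to 2.6 Gy at 0.2-Gy intervals), giving Vx covariates —
percent of organ volume receiving at least x cGy per fraction — which
enter an L1-penalized logistic regression together with the 11 clinical
dummy/continuous covariates.  The penalty strength is chosen by
stratified 10-fold cross-validation maximizing the mean out-of-fold AUC.

Because adjacent Vx columns are almost perfectly collinear, the LASSO
shrinks most coefficients exactly to zero (odds ratio exactly 1) and the
surviving coefficients are unstable under resampling; that instability
is the motivation for the functional approach and is demonstrated (not
asserted) by the bootstrap comparison in the validation machinery.

Implementation: slopes come from scikit-learn's liblinear L1 solver on
internally standardized columns (intercept effectively unpenalized via a
large intercept scaling plus an exact unpenalized 1-D Newton refit of
the intercept at fixed slopes); coefficients are reported back on the
original covariate scale.  λ = 0 falls back to the unpenalized MLE.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .dvh import Cohort, DesignMatrix, build_dose_grid, encode_design, resample_curve

__all__ = [
    "PLRModel",
    "build_plr_design",
    "fit_plr",
    "fit_lasso_at",
    "default_lambda_path",
    "plr_model_to_json",
    "plr_model_from_json",
]

PLR_GRID = build_dose_grid(0.2, 2.6, 0.2)


def _vx_label(d: float) -> str:
    return f"V{int(round(d * 100)):03d}"


VX_COLUMNS = tuple(_vx_label(d) for d in PLR_GRID.points)


def build_plr_design(cohort: Cohort) -> DesignMatrix:
    """13 Vx columns (percent volume, 0-100) + 11 clinical columns."""
    if cohort.grid.d_min > PLR_GRID.d_min or cohort.grid.d_max < PLR_GRID.d_max:
        raise ValueError("cohort grid does not cover the 0.2-2.6 Gy PLR sampling grid")
    vx = np.stack(
        [100.0 * resample_curve(c, PLR_GRID).volume for c in cohort.curves]
    )
    clin = encode_design(cohort.clinical)
    return DesignMatrix(
        column_names=VX_COLUMNS + clin.column_names,
        values=np.column_stack([vx, clin.values]),
        reference_levels=clin.reference_levels,
    )


@dataclass
class PLRModel:
    """Fitted LASSO logistic model with its cross-validation trace."""

    intercept: float
    coefficients: np.ndarray  # original covariate scale
    column_names: tuple
    lambda_: float
    cv_table: Optional[pd.DataFrame]  # columns lambda, mean_auc

    def linear_predictor(self, X: np.ndarray) -> np.ndarray:
        return self.intercept + X @ self.coefficients

    def predict_from_design(self, X: np.ndarray) -> np.ndarray:
        return expit(np.clip(self.linear_predictor(X), -30, 30))

    def predict(self, cohort: Cohort) -> np.ndarray:
        return self.predict_from_design(build_plr_design(cohort).values)

    def odds_ratios(self) -> pd.DataFrame:
        """Per-covariate odds ratios; exact zeros render as OR = 1.0."""
        return pd.DataFrame(
            {"covariate": self.column_names, "odds_ratio": np.exp(self.coefficients)}
        )

    def named_coefficients(self) -> dict:
        out = {"intercept": self.intercept}
        out.update({n: float(b) for n, b in zip(self.column_names, self.coefficients)})
        return out


def _standardize(X: np.ndarray):
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd < 1e-12, 1.0, sd)
    return (X - mu) / sd, mu, sd


def _refit_intercept(Xb: np.ndarray, y: np.ndarray, coefs: np.ndarray) -> float:
    """Exact unpenalized intercept at fixed slopes (damped 1-D Newton)."""
    offset = Xb @ coefs
    prev = float(np.clip(y.mean(), 1e-9, 1 - 1e-9))
    b0 = float(np.log(prev / (1 - prev)))
    for _ in range(100):
        p = expit(np.clip(b0 + offset, -30, 30))
        grad = float(np.sum(y - p))
        hess = float(np.sum(np.clip(p * (1 - p), 1e-10, None)))
        step = float(np.clip(grad / hess, -5.0, 5.0))
        b0 += step
        if abs(step) < 1e-12:
            break
    return b0


def fit_lasso_at(X: np.ndarray, y: np.ndarray, lam: float) -> tuple:
    """L1-penalized logistic fit at one λ; returns (intercept, coefficients).

    Objective: (1/n) Σ logloss + λ ||slopes||_1 on standardized columns,
    intercept unpenalized; coefficients returned on the original scale.
    Exact zeros on the standardized scale stay exact zeros.
    """
    import warnings

    n = len(y)
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    Xs, mu, sd = _standardize(X)
    if lam == 0:
        clf = LogisticRegression(C=np.inf, solver="lbfgs", tol=1e-10, max_iter=2000)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            clf.fit(Xs, y)
        w = clf.coef_[0]
        b0 = float(clf.intercept_[0])
    else:
        clf = LogisticRegression(
            l1_ratio=1.0,
            C=1.0 / (n * lam),
            solver="liblinear",
            intercept_scaling=1000.0,
            tol=1e-8,
            max_iter=2000,
            random_state=0,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            clf.fit(Xs, y)
        w = clf.coef_[0]
        b0 = _refit_intercept(Xs, y, w)
    coefs = w / sd
    intercept = b0 - float(np.dot(w, mu / sd))
    return intercept, coefs


def default_lambda_path(X: np.ndarray, y: np.ndarray, size: int = 100) -> np.ndarray:
    """Log-spaced path from the all-zero-slopes λ down four decades."""
    Xs, _, _ = _standardize(X)
    yc = y - y.mean()
    lam_max = float(np.max(np.abs(Xs.T @ yc)) / len(y))
    return np.geomspace(lam_max, lam_max * 1e-4, size)


def fit_plr(
    cohort: Cohort,
    lambda_path: Optional[np.ndarray] = None,
    folds: int = 10,
    fold_seed: int = 0,
    path_size: int = 100,
) -> PLRModel:
    """Cross-validated LASSO logistic regression on Vx + clinical covariates.

    λ* maximizes the mean out-of-fold AUC over stratified folds (ties go
    to the larger λ, i.e. the sparser model); the final model is refit
    on all data at λ*.
    """
    design = build_plr_design(cohort)
    X, y = design.values, cohort.outcome.astype(float)
    if len(np.unique(y)) < 2:
        raise ValueError("both outcome classes must be present")
    if lambda_path is None:
        lambda_path = default_lambda_path(X, y, path_size)
    lambda_path = np.sort(np.asarray(lambda_path, dtype=float))[::-1]

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=fold_seed)
    aucs = np.zeros((len(lambda_path), folds))
    for f, (tr, te) in enumerate(skf.split(X, y)):
        for i, lam in enumerate(lambda_path):
            b0, w = fit_lasso_at(X[tr], y[tr], lam)
            score = X[te] @ w + b0
            if len(np.unique(y[te])) < 2:
                aucs[i, f] = np.nan
            else:
                aucs[i, f] = roc_auc_score(y[te], score)
    mean_auc = np.nanmean(aucs, axis=1)
    best = np.nanmax(mean_auc)
    # path is sorted descending in lambda, so the first near-max is the sparsest
    idx = int(np.flatnonzero(mean_auc >= best - 1e-12)[0])
    lam_star = float(lambda_path[idx])

    b0, w = fit_lasso_at(X, y, lam_star)
    cv_table = pd.DataFrame({"lambda": lambda_path, "mean_auc": mean_auc})
    return PLRModel(
        intercept=b0,
        coefficients=w,
        column_names=design.column_names,
        lambda_=lam_star,
        cv_table=cv_table,
    )


def plr_model_to_json(model: PLRModel) -> str:
    payload = {
        "model_type": "plr",
        "intercept": model.intercept,
        "column_names": list(model.column_names),
        "coefficients": list(map(float, model.coefficients)),
        "lambda": model.lambda_,
        "basis": None,
        "cv_table": None
        if model.cv_table is None
        else {k: list(map(float, v)) for k, v in model.cv_table.to_dict(orient="list").items()},
    }
    return json.dumps(payload, indent=2, sort_keys=True)


def plr_model_from_json(text: str) -> PLRModel:
    payload = json.loads(text)
    if payload.get("model_type") != "plr":
        raise ValueError("not a PLR model file")
    cv = payload.get("cv_table")
    return PLRModel(
        intercept=float(payload["intercept"]),
        coefficients=np.asarray(payload["coefficients"], dtype=float),
        column_names=tuple(payload["column_names"]),
        lambda_=float(payload["lambda"]),
        cv_table=None if cv is None else pd.DataFrame(cv),
    )
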