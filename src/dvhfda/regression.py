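"""Penalized functional logistic regression and model selection.

The model for patient i combines clinical covariates Z_j with the DVH
curve V_i(d) through a dose-weighting function β(d):

    logit P(y_i = 1) = α + Σ_j β_j Z_j + ∫ β(d) V_i(d) dd
                     ≈ α + Σ_j β_j Z_j + Σ_k β_k c_ik

where β(d) = Σ_k β_k ξ_k(d) is expanded in the leading FPCA or FPLS
components and c_ik are the per-patient component scores.  Fitting is
maximum penalized likelihood via iteratively reweighted least squares
(IRLS), with a roughness penalty (r/2)·β_fᵀ R β_f on the *functional*
coefficients only — R is the Gram matrix of the components' second
derivatives, so large r drives β(d) toward curvature-free shapes.
Clinical coefficients are never penalized.

The number of leading components k_n and the penalty r are chosen by a
BIC-style model selection criterion

    MSC = log[ (1/n) Σ_i (y_i − ŷ_i)² ] + log(n) · df / (n/2)

minimized over candidate (k_n, r) pairs, with ŷ_i the fitted
probability and df the effective degrees of freedom of the penalized
functional block (df = k_n when r = 0, shrinking as r grows, so heavy
smoothing is selectable when it barely costs fit).  Ties go to the
smaller k_n, then the larger r (parsimony and smoothness first).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .dvh import Cohort, DesignMatrix, DoseGrid
from .fpca import FunctionalBasis, as_curve_matrix, fpca_decompose
from .fpls import fpls_decompose

__all__ = [
    "FittedModel",
    "SelectionResult",
    "penalty_matrix",
    "fit_functional_logistic",
    "beta_function",
    "msc_select",
    "predict",
    "bernoulli_loglik",
    "default_r_grid",
    "model_to_json",
    "model_from_json",
]

MAX_ITER = 100
COEF_TOL = 1e-8
ETA_CLIP = 30.0


def default_r_grid() -> np.ndarray:
    """{0} plus 15 log-spaced penalties spanning the working range [0.1, 1350]."""
    return np.concatenate([[0.0], np.geomspace(0.1, 1350.0, 15)])


def second_derivatives(components: np.ndarray, step: float) -> np.ndarray:
    """Row-wise ξ''(d): second-order central differences, one-sided at ends."""
    comps = np.atleast_2d(components)
    if comps.shape[1] < 3:
        raise ValueError("second derivatives need a grid with at least 3 points")
    dd = np.empty_like(comps)
    dd[:, 1:-1] = comps[:, :-2] - 2 * comps[:, 1:-1] + comps[:, 2:]
    dd[:, 0] = comps[:, 0] - 2 * comps[:, 1] + comps[:, 2]
    dd[:, -1] = comps[:, -3] - 2 * comps[:, -2] + comps[:, -1]
    return dd / step**2


def penalty_matrix(basis: FunctionalBasis, k_components: Optional[int] = None) -> np.ndarray:
    """Curvature Gram matrix R_jk = Δd Σ_d ξ_j''(d) ξ_k''(d) (symmetric PSD)."""
    if k_components is None:
        k_components = basis.n_components
    comps = basis.components[:k_components]
    dd = second_derivatives(comps, basis.grid.step)
    return basis.grid.step * dd @ dd.T


def bernoulli_loglik(y: np.ndarray, eta: np.ndarray) -> float:
    """Bernoulli log-likelihood at linear predictor eta (numerically safe)."""
    eta = np.clip(eta, -ETA_CLIP, ETA_CLIP)
    return float(np.sum(y * eta - np.log1p(np.exp(eta))))


@dataclass
class FittedModel:
    """A fitted functional logistic regression model."""

    intercept: float
    clinical_coefficients: np.ndarray
    clinical_names: tuple
    functional_coefficients: np.ndarray
    basis: Optional[FunctionalBasis]
    k_n: int
    r: float
    converged: bool
    n_iterations: int
    #: effective degrees of freedom of the penalized functional block,
    #: tr[(XᵀWX+P)⁻¹XᵀWX] minus the unpenalized block count; equals k_n
    #: exactly at r = 0 and shrinks toward the curvature-free dimension
    #: as r grows.
    edf_functional: float = 0.0

    @property
    def beta_function(self) -> np.ndarray:
        """The implied dose-weighting function β(d) = Σ_k β_k ξ_k(d)."""
        if self.basis is None:
            raise ValueError("model has no functional basis attached")
        return self.functional_coefficients @ self.basis.components[: self.k_n]

    def linear_predictor(self, scores: np.ndarray, design_values: np.ndarray) -> np.ndarray:
        return (
            self.intercept
            + scores[:, : self.k_n] @ self.functional_coefficients
            + design_values @ self.clinical_coefficients
        )

    def named_coefficients(self) -> dict:
        """Flat name -> log-odds coefficient map (for bootstrap OR tables)."""
        out = {"intercept": self.intercept}
        for name, b in zip(self.clinical_names, self.clinical_coefficients):
            out[name] = float(b)
        kind = self.basis.kind if self.basis is not None else "component"
        for k, b in enumerate(self.functional_coefficients, start=1):
            out[f"{kind}_{k}"] = float(b)
        return out


def _collinearity_check(X: np.ndarray, names: Sequence[str]) -> None:
    _, Rmat = np.linalg.qr(X)
    diag = np.abs(np.diag(Rmat))
    bad = diag < 1e-10 * max(diag.max(), 1.0)
    if bad.any():
        offenders = [names[i] for i in np.flatnonzero(bad)]
        raise ValueError(f"collinear design columns: {offenders}")


def fit_functional_logistic(
    scores: np.ndarray,
    design: Optional[DesignMatrix],
    y: np.ndarray,
    r: float = 0.0,
    penalty: Optional[np.ndarray] = None,
    basis: Optional[FunctionalBasis] = None,
    max_iter: int = MAX_ITER,
) -> FittedModel:
    """Penalized-IRLS fit of the functional logistic model.

    Maximizes the Bernoulli log-likelihood minus (r/2)·β_fᵀ R β_f where
    R = ``penalty`` acts on the functional coefficients only.  Perfect
    separation is reported via ``converged=False`` with finite
    coefficients returned at the iteration cap.
    """
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    y = np.asarray(y, dtype=float)
    n, k = scores.shape
    if len(np.unique(y)) < 2:
        raise ValueError("both outcome classes must be present")
    if r < 0:
        raise ValueError("penalty r must be non-negative")
    if basis is not None and penalty is None and r > 0:
        penalty = penalty_matrix(basis, k)
    if r > 0 and penalty is None:
        raise ValueError("a penalty matrix is required when r > 0")

    if design is not None:
        Z = design.values
        # an all-zero dummy column (category absent from this cohort or
        # resample) is unidentifiable: drop it and report coefficient 0
        active = ~np.all(Z == 0, axis=0)
        Z_fit = Z[:, active]
        active_names = [nm for nm, a in zip(design.column_names, active) if a]
        names = ["intercept"] + [f"score_{j + 1}" for j in range(k)] + active_names
        X = np.column_stack([np.ones(n), scores, Z_fit])
    else:
        active = np.zeros(0, dtype=bool)
        names = ["intercept"] + [f"score_{j + 1}" for j in range(k)]
        X = np.column_stack([np.ones(n), scores])
    _collinearity_check(X, names)

    p_total = X.shape[1]
    P = np.zeros((p_total, p_total))
    if r > 0:
        P[1 : 1 + k, 1 : 1 + k] = r * np.asarray(penalty, dtype=float)

    beta = np.zeros(p_total)
    beta[0] = float(np.log(y.mean() / (1 - y.mean())))
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = np.clip(X @ beta, -ETA_CLIP, ETA_CLIP)
        p = expit(eta)
        w = np.clip(p * (1 - p), 1e-10, None)
        z = eta + (y - p) / w
        A = X.T @ (w[:, None] * X) + P
        b = X.T @ (w * z)
        try:
            beta_new = np.linalg.solve(A, b)
        except np.linalg.LinAlgError:
            beta_new = np.linalg.lstsq(A, b, rcond=None)[0]
        delta = np.max(np.abs(beta_new - beta))
        beta = beta_new
        if delta < COEF_TOL:
            converged = True
            break

    # effective df of the functional block at the converged weights
    eta = np.clip(X @ beta, -ETA_CLIP, ETA_CLIP)
    if np.max(np.abs(X @ beta)) >= ETA_CLIP:
        converged = False  # fitted logits at the clip bound: separation
    p = expit(eta)
    w = np.clip(p * (1 - p), 1e-10, None)
    A = X.T @ (w[:, None] * X)
    try:
        df_total = float(np.trace(np.linalg.solve(A + P, A)))
    except np.linalg.LinAlgError:
        df_total = float(p_total)
    edf_functional = df_total - (p_total - k)

    clinical = np.zeros(len(active))
    if design is not None:
        clinical[active] = beta[1 + k :]

    return FittedModel(
        intercept=float(beta[0]),
        clinical_coefficients=clinical,
        clinical_names=tuple(design.column_names) if design is not None else (),
        functional_coefficients=beta[1 : 1 + k].copy(),
        basis=basis,
        k_n=k,
        r=float(r),
        converged=converged,
        n_iterations=it,
        edf_functional=edf_functional,
    )


def beta_function(model: FittedModel) -> np.ndarray:
    """β(d) on the model grid (exact linear combination of components)."""
    return model.beta_function


@dataclass
class SelectionResult:
    """Outcome of the MSC search over (component count, penalty) pairs."""

    candidates: pd.DataFrame  # columns k_n, r, msc, converged
    k_n: int
    r: float
    model: FittedModel
    basis: FunctionalBasis


def msc_value(
    y: np.ndarray, p_hat: np.ndarray, complexity: float, denominator: str = "half_n"
) -> float:
    """BIC-style model selection criterion on the probability scale.

    ``complexity`` is the model-complexity count: the effective degrees
    of freedom of the penalized functional block (equal to the raw
    component count k_n when r = 0).
    """
    n = len(y)
    mse = float(np.mean((y - p_hat) ** 2))
    denom = n / 2 if denominator == "half_n" else float(n)
    return float(np.log(mse) + np.log(n) * complexity / denom)


def msc_select(
    curves,
    y,
    design: Optional[DesignMatrix],
    basis_kind: str = "fpls",
    component_budget: int = 5,
    r_grid: Optional[np.ndarray] = None,
    grid: Optional[DoseGrid] = None,
    msc_denominator: str = "half_n",
    msc_complexity: str = "effective_df",
    basis: Optional[FunctionalBasis] = None,
) -> SelectionResult:
    """Fit all (leading-k components, r) candidates and pick the MSC minimum.

    Candidate component sets are leading prefixes {1}, {1,2}, ... only.
    With ``msc_complexity="effective_df"`` (default) the complexity term
    counts the effective degrees of freedom of the penalized functional
    block, so heavier penalties compete on equal footing (at r = 0 it
    equals the raw component count); ``"component_count"`` uses k_n
    literally, under which the criterion can never prefer r > 0.
    A precomputed ``basis`` may be supplied (it must match
    ``basis_kind``); otherwise components are extracted here.
    """
    X, g = as_curve_matrix(curves, grid)
    y = np.asarray(y, dtype=float)
    n = X.shape[0]
    if r_grid is None:
        r_grid = default_r_grid()
    r_grid = np.asarray(r_grid, dtype=float)
    budget = min(component_budget, min(n - 1, g.size))
    if basis is None:
        if basis_kind == "fpca":
            basis = fpca_decompose(X, k_max=budget, grid=g)
        elif basis_kind == "fpls":
            basis = fpls_decompose(X, y, k_max=budget, grid=g)
        else:
            raise ValueError("basis_kind must be 'fpca' or 'fpls'")
    budget = min(budget, basis.n_components)

    R_full = penalty_matrix(basis, budget)
    rows = []
    fits = {}
    for k in range(1, budget + 1):
        sk = basis.scores[:, :k]
        Rk = R_full[:k, :k]
        for r in r_grid:
            model = fit_functional_logistic(sk, design, y, r=float(r), penalty=Rk, basis=basis)
            eta = model.linear_predictor(sk, design.values if design is not None else np.empty((n, 0)))
            p_hat = expit(np.clip(eta, -ETA_CLIP, ETA_CLIP))
            complexity = model.edf_functional if msc_complexity == "effective_df" else float(k)
            rows.append(
                (k, float(r), msc_value(y, p_hat, complexity, msc_denominator),
                 complexity, model.converged)
            )
            fits[(k, float(r))] = model

    table = pd.DataFrame(rows, columns=["k_n", "r", "msc", "complexity", "converged"])
    best = table["msc"].min()
    near = table[table["msc"] <= best + 1e-12]
    k_sel = int(near["k_n"].min())
    r_sel = float(near[near["k_n"] == k_sel]["r"].max())
    return SelectionResult(
        candidates=table, k_n=k_sel, r=r_sel, model=fits[(k_sel, r_sel)], basis=basis
    )


def predict(model: FittedModel, cohort: Cohort) -> np.ndarray:
    """Predicted severe-toxicity probabilities for a cohort.

    Scores are computed against the *training* mean and components
    stored in the model's basis; the cohort must be on the model grid.
    """
    if model.basis is None:
        raise ValueError("model has no functional basis attached")
    if cohort.grid != model.basis.grid:
        raise ValueError("cohort grid does not match the model grid")
    scores = model.basis.project_scores(cohort.volumes)
    design = cohort.design()
    eta = model.linear_predictor(scores, design.values)
    return expit(np.clip(eta, -ETA_CLIP, ETA_CLIP))


# --------------------------------------------------------------------------
# serialization (flat JSON text; round-trip exact for the stored precision)

def model_to_json(model: FittedModel, selection: Optional[SelectionResult] = None) -> str:
    basis = model.basis
    payload = {
        "model_type": "functional_lr",
        "intercept": model.intercept,
        "clinical_names": list(model.clinical_names),
        "clinical_coefficients": list(map(float, model.clinical_coefficients)),
        "functional_coefficients": list(map(float, model.functional_coefficients)),
        "k_n": model.k_n,
        "r": model.r,
        "converged": model.converged,
        "n_iterations": model.n_iterations,
        "edf_functional": model.edf_functional,
        "basis": None,
    }
    if basis is not None:
        payload["basis"] = {
            "kind": basis.kind,
            "grid": {"d_min": basis.grid.d_min, "d_max": basis.grid.d_max, "step": basis.grid.step},
            "mean_function": list(map(float, basis.mean_function)),
            "components": [list(map(float, row)) for row in basis.components],
            "eigenvalues": list(map(float, basis.eigenvalues)),
            "total_variance": basis.total_variance,
        }
    if selection is not None:
        payload["selection"] = {
            "k_n": selection.k_n,
            "r": selection.r,
            "candidates": selection.candidates.to_dict(orient="list"),
        }
    return json.dumps(payload, indent=2, sort_keys=True)


def model_from_json(text: str) -> FittedModel:
    from .dvh import build_dose_grid

    payload = json.loads(text)
    if payload.get("model_type") != "functional_lr":
        raise ValueError("not a functional logistic regression model file")
    basis = None
    if payload["basis"] is not None:
        b = payload["basis"]
        g = build_dose_grid(b["grid"]["d_min"], b["grid"]["d_max"], b["grid"]["step"])
        comps = np.asarray(b["components"], dtype=float)
        basis = FunctionalBasis(
            grid=g,
            kind=b["kind"],
            components=comps,
            eigenvalues=np.asarray(b["eigenvalues"], dtype=float),
            mean_function=np.asarray(b["mean_function"], dtype=float),
            scores=np.zeros((0, comps.shape[0])),
            total_variance=float(b["total_variance"]),
        )
    return FittedModel(
        intercept=float(payload["intercept"]),
        clinical_coefficients=np.asarray(payload["clinical_coefficients"], dtype=float),
        clinical_names=tuple(payload["clinical_names"]),
        functional_coefficients=np.asarray(payload["functional_coefficients"], dtype=float),
        basis=basis,
        k_n=int(payload["k_n"]),
        r=float(payload["r"]),
        converged=bool(payload["converged"]),
        n_iterations=int(payload["n_iterations"]),
        edf_functional=float(payload.get("edf_functional", 0.0)),
    )
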