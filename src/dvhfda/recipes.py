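"""Self-contained model-building recipes for the validation machinery.

A recipe bundles *everything* needed to build a model from a cohort —
component extraction, hyperparameter tuning, fitting — so the optimism
bootstrap can re-run it honestly on each resample.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .dvh import Cohort
from .plr import PLRModel, fit_plr
from .regression import (
    FittedModel,
    SelectionResult,
    default_r_grid,
    fit_functional_logistic,
    msc_select,
    penalty_matrix,
    predict,
)
from .fpca import fpca_decompose
from .fpls import fpls_decompose

__all__ = [
    "FunctionalLRRecipe",
    "PLRRecipe",
    "ConstantRecipe",
    "InterceptOnlyRecipe",
]


class _FittedFunctional:
    def __init__(self, model: FittedModel, selection: Optional[SelectionResult] = None):
        self.model = model
        self.selection = selection

    def predict(self, cohort: Cohort) -> np.ndarray:
        return predict(self.model, cohort)

    def named_coefficients(self) -> dict:
        return self.model.named_coefficients()


@dataclass
class FunctionalLRRecipe:
    """FPC-LR or FPLS-LR with MSC selection of (k_n, r).

    With ``fixed_k``/``fixed_r`` set, the MSC search is skipped and the
    model is fit directly at those values (useful for fast, targeted
    simulation studies).
    """

    kind: str = "fpls"  # "fpca" | "fpls"
    component_budget: int = 5
    r_grid: np.ndarray = field(default_factory=default_r_grid)
    fixed_k: Optional[int] = None
    fixed_r: Optional[float] = None
    msc_denominator: str = "half_n"

    def fit(self, cohort: Cohort, rng: np.random.Generator) -> _FittedFunctional:
        design = cohort.design()
        y = cohort.outcome.astype(float)
        if self.fixed_k is not None:
            k = min(self.fixed_k, cohort.n - 1)
            if self.kind == "fpca":
                basis = fpca_decompose(cohort.volumes, k_max=k, grid=cohort.grid)
            else:
                basis = fpls_decompose(cohort.volumes, y, k_max=k, grid=cohort.grid)
            r = float(self.fixed_r or 0.0)
            pen = penalty_matrix(basis, k) if r > 0 else None
            model = fit_functional_logistic(
                basis.scores, design, y, r=r, penalty=pen, basis=basis
            )
            return _FittedFunctional(model)
        sel = msc_select(
            cohort.volumes,
            y,
            design,
            basis_kind=self.kind,
            component_budget=self.component_budget,
            r_grid=self.r_grid,
            grid=cohort.grid,
            msc_denominator=self.msc_denominator,
        )
        return _FittedFunctional(sel.model, sel)


class _FittedPLR:
    def __init__(self, model: PLRModel):
        self.model = model

    def predict(self, cohort: Cohort) -> np.ndarray:
        return self.model.predict(cohort)

    def named_coefficients(self) -> dict:
        return self.model.named_coefficients()


@dataclass
class PLRRecipe:
    """LASSO logistic regression with per-fit 10-fold CV tuning of λ."""

    folds: int = 10
    path_size: int = 100

    def fit(self, cohort: Cohort, rng: np.random.Generator) -> _FittedPLR:
        fold_seed = int(rng.integers(2**31))
        return _FittedPLR(
            fit_plr(cohort, folds=self.folds, fold_seed=fold_seed, path_size=self.path_size)
        )


class _FittedConstant:
    def __init__(self, c: float, name: str = "constant"):
        self.c = c
        self.name = name

    def predict(self, cohort: Cohort) -> np.ndarray:
        return np.full(cohort.n, self.c)

    def named_coefficients(self) -> dict:
        return {self.name: 0.0}


@dataclass
class ConstantRecipe:
    """Predicts a fixed probability; no fitting, hence no optimism."""

    c: float = 0.5

    def fit(self, cohort: Cohort, rng: np.random.Generator) -> _FittedConstant:
        return _FittedConstant(self.c)


@dataclass
class InterceptOnlyRecipe:
    """Predicts the training prevalence for everyone."""

    def fit(self, cohort: Cohort, rng: np.random.Generator) -> _FittedConstant:
        return _FittedConstant(float(cohort.outcome.mean()), name="intercept")
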