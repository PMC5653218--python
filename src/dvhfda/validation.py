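"""Model validation: discrimination, calibration, optimism bootstrap, OR CIs.

Internal validation follows the Efron optimism-bootstrap procedure: the
*full* model-building recipe (including any hyperparameter tuning, MSC
or cross-validation) is re-run from scratch on every bootstrap resample;
each metric is evaluated on the resample (M_boot) and on the original
cohort (M_orig), and

    optimism  O = (1/B) Σ_b (M_b,boot − M_b,orig)
    corrected   = M_apparent − O.

Odds-ratio uncertainty uses the percentile bootstrap of the fitted
coefficients over the same kind of replicates; a covariate absent from a
replicate's selected model (a component dropped by MSC, a column zeroed
by the LASSO) contributes an odds ratio of exactly 1 for that replicate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Protocol, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import logit
from sklearn.metrics import roc_auc_score

from .dvh import Cohort

__all__ = [
    "auc",
    "brier",
    "calibration",
    "CalibrationResult",
    "ValidationReport",
    "optimism_correct",
    "bootstrap_or_ci",
    "external_validate",
    "ModelRecipe",
]

P_CLIP = 1e-8
METRIC_NAMES = ("auc", "brier", "calibration_slope", "calibration_intercept")


def auc(y, p) -> float:
    """Probability that a random positive outranks a random negative.

    Mann-Whitney convention: ties count 1/2.
    """
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("AUC needs both outcome classes")
    return float(roc_auc_score(y, np.asarray(p, dtype=float)))


def brier(y, p) -> float:
    """Mean squared error between predicted probability and outcome."""
    y = np.asarray(y, dtype=float)
    p = np.asarray(p, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("probabilities must lie in [0, 1]")
    return float(np.mean((p - y) ** 2))


@dataclass(frozen=True)
class CalibrationResult:
    slope: float
    intercept: float
    n_clipped: int

    def __iter__(self):
        return iter((self.slope, self.intercept))


def calibration(y, p, intercept_convention: str = "joint") -> CalibrationResult:
    """Logistic recalibration of outcomes against logit(predicted p).

    slope < 1 indicates overfitting (predictions too extreme), slope > 1
    underfitting.  With ``intercept_convention="joint"`` (default) slope
    and intercept come from the same two-parameter fit, the intercept
    being the log-odds at logit(p) = 0; with ``"fixed_slope"`` the
    intercept is calibration-in-the-large, refit with the slope fixed
    at 1 (offset model).  Degenerate constant predictions give NaNs.
    """
    y = np.asarray(y, dtype=float)
    p = np.asarray(p, dtype=float)
    n_clipped = int(np.sum((p < P_CLIP) | (p > 1 - P_CLIP)))
    L = logit(np.clip(p, P_CLIP, 1 - P_CLIP))
    if np.ptp(L) < 1e-12 or len(np.unique(y)) < 2:
        return CalibrationResult(np.nan, np.nan, n_clipped)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # separation in bootstrap replicates
        fit = sm.GLM(y, sm.add_constant(L), family=sm.families.Binomial()).fit()
    slope = float(fit.params[1])
    if intercept_convention == "joint":
        intercept = float(fit.params[0])
    elif intercept_convention == "fixed_slope":
        off = sm.GLM(y, np.ones((len(y), 1)), family=sm.families.Binomial(), offset=L).fit()
        intercept = float(off.params[0])
    else:
        raise ValueError("intercept_convention must be 'joint' or 'fixed_slope'")
    return CalibrationResult(slope, intercept, n_clipped)


class ModelRecipe(Protocol):
    """A self-contained fit procedure (including any tuning).

    ``fit`` must run the entire model-building pipeline from scratch on
    the given cohort; the returned object exposes ``predict(cohort)``
    returning probabilities and ``named_coefficients()`` returning a
    flat name -> log-odds map.
    """

    def fit(self, cohort: Cohort, rng: np.random.Generator): ...


def _metrics(y, p) -> dict:
    cal = calibration(y, p)
    try:
        a = auc(y, p)
    except ValueError:
        a = np.nan
    return {
        "auc": a,
        "brier": brier(y, p),
        "calibration_slope": cal.slope,
        "calibration_intercept": cal.intercept,
    }


@dataclass
class ValidationReport:
    """Apparent / optimism / corrected triples plus the replicate trace."""

    apparent: dict
    optimism: dict
    corrected: dict
    B: int
    replicates: pd.DataFrame  # per replicate: <metric>_boot, <metric>_orig
    n_redrawn: int

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "metric": list(METRIC_NAMES),
                "apparent": [self.apparent[m] for m in METRIC_NAMES],
                "optimism": [self.optimism[m] for m in METRIC_NAMES],
                "corrected": [self.corrected[m] for m in METRIC_NAMES],
            }
        )


def _bootstrap_indices(
    cohort: Cohort, rng: np.random.Generator, max_draws: int, stratified: bool = False
):
    """Resample n patients with replacement; redraw if one outcome class.

    Plain (unstratified) resampling is the default, matching the
    standard Efron optimism procedure; ``stratified=True`` resamples
    within each outcome class, preserving the event count.
    """
    if stratified:
        pos = np.flatnonzero(cohort.outcome == 1)
        neg = np.flatnonzero(cohort.outcome == 0)
        idx = np.concatenate(
            [pos[rng.integers(0, len(pos), len(pos))], neg[rng.integers(0, len(neg), len(neg))]]
        )
        return idx, 0
    redrawn = 0
    for _ in range(max_draws):
        idx = rng.integers(0, cohort.n, size=cohort.n)
        if len(np.unique(cohort.outcome[idx])) == 2:
            return idx, redrawn
        redrawn += 1
    raise RuntimeError("could not draw a two-class bootstrap resample")


def optimism_correct(
    model_recipe: ModelRecipe,
    cohort: Cohort,
    B: int = 2000,
    seed: int = 0,
    stratified: bool = False,
) -> ValidationReport:
    """Optimism-corrected AUC, Brier and calibration via the bootstrap.

    The recipe is re-fit in full on each of the ``B`` resamples
    (nested hyperparameter tuning included), so no tuning information
    leaks from the training data into the internal validation.
    Single-class resamples are redrawn (capped at 2B draws total).
    """
    ss = np.random.SeedSequence(seed)
    fit_rng, boot_rng = (np.random.default_rng(s) for s in ss.spawn(2))

    apparent_fit = model_recipe.fit(cohort, fit_rng)
    apparent = _metrics(cohort.outcome, apparent_fit.predict(cohort))

    rows = []
    n_redrawn = 0
    budget = 2 * B
    for _ in range(B):
        idx, redrawn = _bootstrap_indices(cohort, boot_rng, budget, stratified)
        n_redrawn += redrawn
        budget -= redrawn
        boot = cohort.subset(idx)
        fitted = model_recipe.fit(boot, np.random.default_rng(boot_rng.integers(2**31)))
        m_boot = _metrics(boot.outcome, fitted.predict(boot))
        m_orig = _metrics(cohort.outcome, fitted.predict(cohort))
        rows.append(
            {f"{k}_boot": m_boot[k] for k in METRIC_NAMES}
            | {f"{k}_orig": m_orig[k] for k in METRIC_NAMES}
        )
    reps = pd.DataFrame(rows)
    optimism = {}
    for m in METRIC_NAMES:
        diffs = (reps[f"{m}_boot"] - reps[f"{m}_orig"]).to_numpy()
        valid = diffs[np.isfinite(diffs)]
        optimism[m] = float(valid.mean()) if valid.size else float("nan")
    corrected = {m: apparent[m] - optimism[m] for m in METRIC_NAMES}
    return ValidationReport(
        apparent=apparent,
        optimism=optimism,
        corrected=corrected,
        B=B,
        replicates=reps,
        n_redrawn=n_redrawn,
    )


def bootstrap_or_ci(
    model_recipe: ModelRecipe,
    cohort: Cohort,
    B: int = 2000,
    seed: int = 0,
    covariates: Optional[Sequence[str]] = None,
    stratified: bool = False,
) -> pd.DataFrame:
    """Percentile-bootstrap 95% confidence intervals for odds ratios.

    Returns a table with columns covariate, odds_ratio (full-data fit),
    ci_low, ci_high, significant (1 outside the interval).  Covariates
    the recipe drops in a replicate (component not selected, coefficient
    zeroed) enter that replicate with OR = 1.
    """
    ss = np.random.SeedSequence(seed)
    fit_rng, boot_rng = (np.random.default_rng(s) for s in ss.spawn(2))
    full_fit = model_recipe.fit(cohort, fit_rng)
    point = full_fit.named_coefficients()
    if covariates is None:
        covariates = list(point)

    draws = np.zeros((B, len(covariates)))
    budget = 2 * B
    for b in range(B):
        idx, redrawn = _bootstrap_indices(cohort, boot_rng, budget, stratified)
        budget -= redrawn
        fitted = model_recipe.fit(
            cohort.subset(idx), np.random.default_rng(boot_rng.integers(2**31))
        )
        coefs = fitted.named_coefficients()
        draws[b] = [coefs.get(name, 0.0) for name in covariates]

    ors = np.exp(np.clip(draws, -700, 700))  # separation replicates stay finite
    # canonical percentile-interval convention: the (B+1)*alpha-th order
    # statistics, not interpolated quantiles (which narrow the interval
    # at moderate B)
    lo = np.percentile(ors, 2.5, axis=0, method="lower")
    hi = np.percentile(ors, 97.5, axis=0, method="higher")
    point_or = np.array([np.exp(point.get(name, 0.0)) for name in covariates])
    return pd.DataFrame(
        {
            "covariate": list(covariates),
            "odds_ratio": point_or,
            "ci_low": lo,
            "ci_high": hi,
            "significant": (lo > 1.0) | (hi < 1.0),
        }
    )


def external_validate(fitted_model, external_cohort: Cohort) -> dict:
    """Frozen-model metrics on an external cohort (no refitting).

    ``fitted_model`` only needs a ``predict(cohort)`` method; the
    training-derived mean function, components and coefficients inside
    it are used untouched.
    """
    p = fitted_model.predict(external_cohort)
    return _metrics(external_cohort.outcome, p)
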