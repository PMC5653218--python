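"""Synthetic DVH cohort generator with known ground truth.

Real head-and-neck mucosal DVHs are smooth, monotone-non-increasing
curves whose dominant between-patient variation comes from how much of
the organ at risk overlaps the two planning target volumes (prescribed
at two fractional-dose levels, e.g. 1.8 and 2.1 Gy/fraction).  The
generator reproduces that structure with a two-sigmoid-shoulder curve
family plus a small amount of smooth noise:

    V(d) = (1 - f) * S(d; c_low) + f * S(d; c_high)

where ``f`` is a per-patient Beta-distributed overlap fraction, ``S`` a
sigmoidal shoulder, and the shoulder centers jitter around the two
prescription levels.  Adjacent dose levels are therefore very highly
correlated across patients, as in clinical DVH data.

Outcomes follow a functional logistic model with a known dose-weighting
function β*(d) and known clinical coefficients:

    logit P(y=1) = α + Σ_j β_j Z_j + Δd Σ_k β*(d_k) V(d_k)

so fitted models can be tested for parameter recovery.  The same
left-Riemann quadrature is used by the generator and the estimators.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit

from .dvh import (
    DESIGN_COLUMNS,
    ClinicalCovariates,
    Cohort,
    DoseGrid,
    DVHCurve,
    build_dose_grid,
    encode_design,
)

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "generate_curve",
    "generate_cohort",
    "preset_mucositis_like",
    "preset_dysphagia_like",
    "monotone_dose_weighting",
]

#: Default marginal frequencies of the categorical clinical covariates.
#: The originating cohorts' joint distribution is not public; these are
#: plausible head-and-neck trial marginals.
DEFAULT_MARGINALS = {
    "sex": {"male": 0.7, "female": 0.3},
    "rt_intent": {"definitive": 0.8, "postoperative": 0.2},
    "induction_chemo": {"yes": 0.5, "no": 0.5},
    "concurrent_chemo": {"none": 0.30, "cisplatin": 0.45, "carboplatin": 0.15, "cis_carbo": 0.10},
    "primary_site": {
        "oropharynx_oral_cavity": 0.50,
        "nasopharynx_nasal_cavity": 0.12,
        "hypopharynx_larynx": 0.20,
        "parotid": 0.08,
        "unknown_primary": 0.10,
    },
    "age_mean": 60.0,
    "age_sd": 8.0,
}


def monotone_dose_weighting(
    grid: DoseGrid,
    scale: float = 3.0,
    center: float = 1.0,
    width: float = 0.25,
    edge_taper: Optional[tuple] = (2.45, 0.08),
) -> np.ndarray:
    """Dose-weighting function β*(d): a monotone-increasing logistic ramp.

    Doses above ~``center`` Gy/fraction carry most of the toxicity
    weight, consistent with high/intermediate fractional doses driving
    severe mucosal toxicity; the ramp is non-decreasing below 2.0 Gy.
    ``edge_taper=(c, w)`` rolls the weighting off over the last fraction
    of the grid, beyond the maximum dose any tissue receives: a true
    weighting supported where the curves actually vary keeps the
    recovery estimand well defined (no estimator has information about
    dose levels never delivered).  Pass ``edge_taper=None`` for a pure
    ramp.
    """
    beta = scale * expit((grid.points - center) / width)
    if edge_taper is not None:
        c, w = edge_taper
        beta = beta * expit((c - grid.points) / w)
    return beta


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic cohort."""

    n_patients: int
    grid: DoseGrid
    prescription_doses: tuple = (1.8, 2.1)
    overlap_alpha: float = 2.0  # Beta law of the target-overlap fraction
    overlap_beta: float = 2.0
    curve_smoothness: float = 0.10  # sigmoid shoulder width, Gy (smaller = steeper)
    # per-shoulder center jitter SD, Gy: the low (elective) level varies a lot
    # across pooled trials with different fractionation, the high (boost) level
    # varies less (hot-spot scale)
    center_jitter_sd: tuple = (0.30, 0.12)
    width_jitter_sd: float = 0.30  # lognormal sigma of the shoulder widths
    noise_sd: float = 0.05  # amplitude of smooth idiosyncratic curve variation
    true_beta: Optional[np.ndarray] = None  # β*(d) on grid; None = zero
    true_clinical_coefficients: np.ndarray = field(
        default_factory=lambda: np.zeros(len(DESIGN_COLUMNS))
    )
    true_intercept: Optional[float] = 0.0  # log-odds; None with target_prevalence set
    target_prevalence: Optional[float] = None
    age_centering: float = 60.0  # age enters the truth centered, years
    marginals: dict = field(default_factory=lambda: dict(DEFAULT_MARGINALS))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ValueError("n_patients must be >= 2")
        lo, hi = self.prescription_doses
        if not (self.grid.d_min <= lo < hi <= self.grid.d_max):
            raise ValueError("prescription doses must lie within the grid span, low < high")
        if self.true_beta is not None:
            self.true_beta = np.asarray(self.true_beta, dtype=float)
            if self.true_beta.shape != (self.grid.size,):
                raise ValueError("true_beta must be defined on the grid")
        if self.true_intercept is None and self.target_prevalence is None:
            raise ValueError("either true_intercept or target_prevalence must be given")


@dataclass
class GroundTruth:
    """What the generator knows and the estimators try to recover."""

    true_beta: np.ndarray
    true_clinical_coefficients: np.ndarray
    true_intercept: float
    linear_predictor: np.ndarray  # per patient, log-odds
    overlap_fractions: np.ndarray


def _shoulder(d: np.ndarray, center, width) -> np.ndarray:
    return expit((np.asarray(center)[..., None] - d) / np.asarray(width)[..., None])


def _generate_volumes(config: SimulationConfig, rng: np.random.Generator, n: int):
    """Vectorized curve generation: returns (n x grid, overlap fractions)."""
    d = config.grid.points
    c_low, c_high = config.prescription_doses
    f = rng.beta(config.overlap_alpha, config.overlap_beta, size=n)
    jit = rng.normal(0.0, 1.0, size=(n, 2)) * np.asarray(config.center_jitter_sd)
    width = config.curve_smoothness * np.exp(
        rng.normal(0.0, config.width_jitter_sd, size=(n, 2))
    )
    low = _shoulder(d, c_low + jit[:, 0], width[:, 0])
    high = _shoulder(d, c_high + jit[:, 1], width[:, 1])
    v = (1.0 - f)[:, None] * low + f[:, None] * high
    # smooth low-frequency noise, vanishing at d_min so V(0) stays 1
    span = config.grid.d_max - config.grid.d_min
    phase = np.pi * (d - config.grid.d_min) / span
    basis = np.sin(np.outer(np.arange(1, 4), phase))  # 3 x grid
    v = v + (rng.normal(0.0, config.noise_sd, size=(n, 3)) / np.arange(1, 4)) @ basis
    # repair to the DVH invariants: bounded, non-increasing, V(0)=1
    v = np.clip(v, 0.0, 1.0)
    if abs(config.grid.d_min) < 1e-12:
        v[:, 0] = 1.0
    v = np.minimum.accumulate(v, axis=1)
    return v, f


def generate_curve(
    config: SimulationConfig,
    rng: np.random.Generator,
    overlap_fraction: Optional[float] = None,
) -> DVHCurve:
    """Draw one synthetic DVH curve.

    ``overlap_fraction`` overrides the Beta draw (useful for probing the
    limiting single-shoulder / step-curve behavior).
    """
    if overlap_fraction is None:
        volumes, _ = _generate_volumes(config, rng, 1)
        return DVHCurve(grid=config.grid, volume=volumes[0])
    cfg = replace(config)
    d = config.grid.points
    c_low, c_high = config.prescription_doses
    w = config.curve_smoothness
    f = float(overlap_fraction)
    v = (1.0 - f) * expit((c_low - d) / w) + f * expit((c_high - d) / w)
    v = np.clip(v, 0.0, 1.0)
    if abs(cfg.grid.d_min) < 1e-12:
        v[0] = 1.0
    v = np.minimum.accumulate(v)
    return DVHCurve(grid=config.grid, volume=v)


def _sample_categorical(rng, levels_probs: dict, n: int):
    levels = list(levels_probs)
    p = np.array([levels_probs[k] for k in levels], dtype=float)
    p = p / p.sum()
    return rng.choice(levels, size=n, p=p)


def _sample_clinical(config: SimulationConfig, rng: np.random.Generator):
    m = config.marginals
    n = config.n_patients
    sex = _sample_categorical(rng, m["sex"], n)
    intent = _sample_categorical(rng, m["rt_intent"], n)
    induction = _sample_categorical(rng, m["induction_chemo"], n)
    chemo = _sample_categorical(rng, m["concurrent_chemo"], n)
    site = _sample_categorical(rng, m["primary_site"], n)
    age = rng.normal(m["age_mean"], m["age_sd"], size=n)
    return [
        ClinicalCovariates(
            sex=sex[i],
            age=float(np.round(age[i], 1)),
            rt_intent=intent[i],
            induction_chemo=induction[i],
            concurrent_chemo=chemo[i],
            primary_site=site[i],
        )
        for i in range(n)
    ]


def generate_cohort(config: SimulationConfig):
    """Generate a cohort plus its ground truth.

    Returns ``(Cohort, GroundTruth)``.  Outcomes are Bernoulli with
    logit ``α + Z β_clin + Δd Σ β*(d) V(d)`` (left-Riemann quadrature,
    age centered at ``config.age_centering``).  If
    ``config.target_prevalence`` is set, the intercept is found by
    root-finding so the cohort-average outcome probability matches it.
    """
    rng = np.random.default_rng(config.seed)
    volumes, overlap = _generate_volumes(config, rng, config.n_patients)
    clinical = _sample_clinical(config, rng)
    design = encode_design(clinical)

    beta_star = (
        config.true_beta if config.true_beta is not None else np.zeros(config.grid.size)
    )
    z = design.values.copy()
    age_col = list(DESIGN_COLUMNS).index("age")
    z[:, age_col] -= config.age_centering
    eta_rest = z @ config.true_clinical_coefficients + config.grid.step * volumes @ beta_star

    if config.target_prevalence is not None:
        target = config.target_prevalence
        alpha = brentq(lambda a: float(np.mean(expit(a + eta_rest))) - target, -40.0, 40.0)
    else:
        alpha = float(config.true_intercept)

    eta = alpha + eta_rest
    y = (rng.random(config.n_patients) < expit(eta)).astype(int)

    cohort = Cohort(
        patient_ids=[f"P{i + 1:04d}" for i in range(config.n_patients)],
        grid=config.grid,
        volumes=volumes,
        clinical=clinical,
        outcome=y,
    )
    truth = GroundTruth(
        true_beta=np.asarray(beta_star, dtype=float),
        true_clinical_coefficients=np.asarray(config.true_clinical_coefficients, dtype=float),
        true_intercept=alpha,
        linear_predictor=eta,
        overlap_fractions=overlap,
    )
    return cohort, truth


#: Clinical log-odds used by the presets (DESIGN_COLUMNS order).  The
#: cisplatin effect is deliberately strong (log-OR 1.4) and the
#: induction-chemotherapy effect is exactly null, so power and coverage
#: of the bootstrap odds-ratio intervals can both be exercised.
PRESET_CLINICAL_COEFFICIENTS = np.array(
    [0.3, 0.0, 0.2, 0.0, 1.4, 0.5, 0.3, 0.3, 0.2, 0.0, -0.3]
)


def _preset(n_patients: int, seed: int, prevalence: float) -> SimulationConfig:
    grid = build_dose_grid(0.0, 2.60, 0.01)
    return SimulationConfig(
        n_patients=n_patients,
        grid=grid,
        true_beta=monotone_dose_weighting(grid),
        true_clinical_coefficients=PRESET_CLINICAL_COEFFICIENTS.copy(),
        true_intercept=None,
        target_prevalence=prevalence,
        seed=seed,
    )


def preset_mucositis_like(n_patients: int = 200, seed: int = 0) -> SimulationConfig:
    """Cohort conditions emulating severe acute mucositis (prevalence 0.73)."""
    return _preset(n_patients, seed, 0.73)


def preset_dysphagia_like(n_patients: int = 200, seed: int = 0) -> SimulationConfig:
    """Cohort conditions emulating severe acute dysphagia (prevalence 0.66)."""
    return _preset(n_patients, seed, 0.66)
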