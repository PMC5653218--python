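"""Data model and I/O for fractional-dose DVH cohorts.

A normalized cumulative dose-volume histogram (DVH) is the curve
``V(d)`` giving the fraction of an organ at risk receiving at least dose
``d``.  Toxicity of radiotherapy developing during treatment tracks the
*fractional* dose distribution (physical dose divided by the number of
fractions), so all grids here are in Gy per fraction.

Every patient's curve lives on one shared, uniformly spaced dose grid;
clinical covariates are categorical/continuous treatment descriptors and
the outcome is a binary severe-toxicity indicator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DoseGrid",
    "DVHCurve",
    "ClinicalCovariates",
    "Cohort",
    "DesignMatrix",
    "build_dose_grid",
    "to_fractional_dose",
    "cumulative_dvh",
    "resample_curve",
    "encode_design",
    "read_cohort",
    "write_cohort",
    "DESIGN_COLUMNS",
    "SEX_LEVELS",
    "RT_INTENT_LEVELS",
    "YES_NO_LEVELS",
    "CONCURRENT_CHEMO_LEVELS",
    "PRIMARY_SITE_LEVELS",
]

_TOL = 1e-9

SEX_LEVELS = ("male", "female")
RT_INTENT_LEVELS = ("definitive", "postoperative")
YES_NO_LEVELS = ("yes", "no")
CONCURRENT_CHEMO_LEVELS = ("none", "cisplatin", "carboplatin", "cis_carbo")
PRIMARY_SITE_LEVELS = (
    "oropharynx_oral_cavity",
    "nasopharynx_nasal_cavity",
    "hypopharynx_larynx",
    "parotid",
    "unknown_primary",
)

#: Reference levels dropped from the dummy coding to avoid perfect
#: collinearity with the intercept: primary site oropharynx/oral cavity
#: and no concurrent chemotherapy.
REFERENCE_LEVELS = {
    "primary_site": "oropharynx_oral_cavity",
    "concurrent_chemo": "none",
}

#: Clinical design columns, in the conventional reporting order.
DESIGN_COLUMNS = (
    "male",
    "age",
    "definitive_rt",
    "induction_chemo",
    "cisplatin",
    "carboplatin",
    "cis_carbo",
    "hypopharynx_larynx",
    "nasopharynx_nasal_cavity",
    "unknown_primary",
    "parotid",
)


@dataclass(frozen=True)
class DoseGrid:
    """Uniform fractional-dose sampling lattice, in Gy."""

    d_min: float
    d_max: float
    step: float
    points: np.ndarray

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        object.__setattr__(self, "points", pts)
        if pts.ndim != 1 or pts.size < 1:
            raise ValueError("grid needs at least one point")
        if np.any(np.diff(pts) <= 0):
            raise ValueError("grid points must be strictly increasing")

    @property
    def size(self) -> int:
        return self.points.size

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DoseGrid):
            return NotImplemented
        return self.points.size == other.points.size and np.allclose(
            self.points, other.points, atol=1e-12
        )

    def __hash__(self) -> int:  # frozen dataclass with array field
        return hash((self.d_min, self.d_max, self.step, self.points.size))


def build_dose_grid(d_min: float, d_max: float, step: float) -> DoseGrid:
    """Build a uniform dose grid from ``d_min`` to ``d_max`` (inclusive).

    The span must be an integer multiple of ``step`` (within floating
    tolerance); e.g. ``build_dose_grid(0, 2.60, 0.01)`` gives 261 points.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    if d_max < d_min:
        raise ValueError("d_max must be >= d_min")
    span = d_max - d_min
    n_steps = span / step
    remainder = abs(n_steps - round(n_steps)) * step
    if remainder > 1e-6 * max(1.0, step):
        raise ValueError(
            f"span {span} Gy is not an integer multiple of step {step} Gy "
            f"(remainder {remainder:.3g} Gy)"
        )
    count = int(round(n_steps)) + 1
    points = d_min + step * np.arange(count)
    if count > 1:
        points[-1] = d_max  # exact endpoint
    return DoseGrid(d_min=float(d_min), d_max=float(d_max), step=float(step), points=points)


@dataclass(frozen=True)
class DVHCurve:
    """One patient's normalized cumulative DVH on a shared grid.

    ``volume[k]`` is the fraction of the organ receiving at least
    ``grid.points[k]`` Gy per fraction; non-increasing and in [0, 1].
    """

    grid: DoseGrid
    volume: np.ndarray

    def __post_init__(self) -> None:
        vol = np.asarray(self.volume, dtype=float)
        object.__setattr__(self, "volume", vol)
        if vol.shape != (self.grid.size,):
            raise ValueError("volume length must match grid size")
        if np.any(vol < -_TOL) or np.any(vol > 1 + _TOL):
            raise ValueError("volume fractions must lie in [0, 1]")
        if np.any(np.diff(vol) > _TOL):
            raise ValueError("cumulative DVH must be non-increasing in dose")
        if abs(self.grid.d_min) < _TOL and abs(vol[0] - 1.0) > _TOL:
            raise ValueError("volume at d=0 must equal 1 for a normalized DVH")


def to_fractional_dose(physical_doses, n_fractions: int):
    """Convert physical doses (Gy) to Gy per fraction."""
    if n_fractions < 1:
        raise ValueError("n_fractions must be >= 1")
    doses = np.asarray(physical_doses, dtype=float)
    if np.any(doses < 0):
        raise ValueError("doses must be non-negative")
    out = doses / n_fractions
    return float(out) if np.isscalar(physical_doses) else out


def cumulative_dvh(dose_samples, grid: DoseGrid) -> DVHCurve:
    """Normalized cumulative DVH of equal-volume dose samples.

    ``volume[k]`` = fraction of samples with dose >= ``grid.points[k]``
    (ties at a grid point count as receiving the dose).
    """
    samples = np.asarray(dose_samples, dtype=float)
    if samples.size == 0:
        raise ValueError("at least one dose sample is required")
    if np.any(samples < 0):
        raise ValueError("dose samples must be non-negative")
    s = np.sort(samples)
    # fraction with dose >= d: count strictly below d, complement
    below = np.searchsorted(s, grid.points, side="left")
    volume = (samples.size - below) / samples.size
    return DVHCurve(grid=grid, volume=volume)


def resample_curve(curve: DVHCurve, target: DoseGrid) -> DVHCurve:
    """Linearly interpolate a DVH onto a new grid (no extrapolation)."""
    src = curve.grid
    if target.d_min < src.d_min - _TOL or target.d_max > src.d_max + _TOL:
        raise ValueError(
            f"target grid [{target.d_min}, {target.d_max}] extends outside "
            f"source grid [{src.d_min}, {src.d_max}]; extrapolation refused"
        )
    volume = np.interp(target.points, src.points, curve.volume)
    return DVHCurve(grid=target, volume=volume)


@dataclass(frozen=True)
class ClinicalCovariates:
    """Treatment and patient descriptors entering the models."""

    sex: str
    age: float
    rt_intent: str
    induction_chemo: str
    concurrent_chemo: str
    primary_site: str

    def __post_init__(self) -> None:
        for name, value, levels in (
            ("sex", self.sex, SEX_LEVELS),
            ("rt_intent", self.rt_intent, RT_INTENT_LEVELS),
            ("induction_chemo", self.induction_chemo, YES_NO_LEVELS),
            ("concurrent_chemo", self.concurrent_chemo, CONCURRENT_CHEMO_LEVELS),
            ("primary_site", self.primary_site, PRIMARY_SITE_LEVELS),
        ):
            if value not in levels:
                raise ValueError(f"unknown {name} category {value!r}; expected one of {levels}")


@dataclass(frozen=True)
class DesignMatrix:
    """Numeric design matrix with named columns and recorded reference levels."""

    column_names: tuple
    values: np.ndarray
    reference_levels: dict = field(default_factory=lambda: dict(REFERENCE_LEVELS))

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "column_names", tuple(self.column_names))
        if vals.ndim != 2 or vals.shape[1] != len(self.column_names):
            raise ValueError("values shape must match column_names")

    @property
    def n(self) -> int:
        return self.values.shape[0]


def encode_design(clinical: Sequence[ClinicalCovariates]) -> DesignMatrix:
    """Dummy (one-hot-minus-reference) coding of clinical covariates.

    Reference levels (female sex, postoperative RT, no induction chemo,
    no concurrent chemo, oropharynx/oral-cavity primary) are dropped so
    that the design plus intercept is full rank.  Age stays continuous,
    in years.
    """
    rows = np.empty((len(clinical), len(DESIGN_COLUMNS)))
    for i, c in enumerate(clinical):
        rows[i] = [
            1.0 if c.sex == "male" else 0.0,
            float(c.age),
            1.0 if c.rt_intent == "definitive" else 0.0,
            1.0 if c.induction_chemo == "yes" else 0.0,
            1.0 if c.concurrent_chemo == "cisplatin" else 0.0,
            1.0 if c.concurrent_chemo == "carboplatin" else 0.0,
            1.0 if c.concurrent_chemo == "cis_carbo" else 0.0,
            1.0 if c.primary_site == "hypopharynx_larynx" else 0.0,
            1.0 if c.primary_site == "nasopharynx_nasal_cavity" else 0.0,
            1.0 if c.primary_site == "unknown_primary" else 0.0,
            1.0 if c.primary_site == "parotid" else 0.0,
        ]
    return DesignMatrix(column_names=DESIGN_COLUMNS, values=rows)


@dataclass
class Cohort:
    """A modeling cohort: DVH matrix, clinical covariates, binary outcomes."""

    patient_ids: list
    grid: DoseGrid
    volumes: np.ndarray  # n_patients x grid.size
    clinical: list  # of ClinicalCovariates
    outcome: np.ndarray  # binary, 1 = severe toxicity

    def __post_init__(self) -> None:
        self.volumes = np.asarray(self.volumes, dtype=float)
        self.outcome = np.asarray(self.outcome, dtype=int)
        n = len(self.patient_ids)
        if not (self.volumes.shape == (n, self.grid.size) and len(self.clinical) == n and self.outcome.shape == (n,)):
            raise ValueError("cohort components must have equal patient counts")
        if not np.all(np.isin(self.outcome, (0, 1))):
            raise ValueError("outcome must be binary (0/1)")
        for pid, row in zip(self.patient_ids, self.volumes):
            _validate_dvh_row(pid, row, self.grid)

    @property
    def n(self) -> int:
        return len(self.patient_ids)

    @property
    def curves(self) -> list:
        return [DVHCurve(grid=self.grid, volume=row) for row in self.volumes]

    def design(self) -> DesignMatrix:
        return encode_design(self.clinical)

    def subset(self, indices: Iterable[int]) -> "Cohort":
        """Row subset / resample (used by the bootstrap machinery)."""
        idx = np.asarray(list(indices), dtype=int)
        return Cohort(
            patient_ids=[f"{self.patient_ids[i]}" for i in idx],
            grid=self.grid,
            volumes=self.volumes[idx],
            clinical=[self.clinical[i] for i in idx],
            outcome=self.outcome[idx],
        )

    def clinical_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "patient_id": self.patient_ids,
                "sex": [c.sex for c in self.clinical],
                "age": [c.age for c in self.clinical],
                "rt_intent": [c.rt_intent for c in self.clinical],
                "induction_chemo": [c.induction_chemo for c in self.clinical],
                "concurrent_chemo": [c.concurrent_chemo for c in self.clinical],
                "primary_site": [c.primary_site for c in self.clinical],
                "outcome": self.outcome,
            }
        )


def _validate_dvh_row(pid, row: np.ndarray, grid: DoseGrid) -> None:
    if np.any(row < -_TOL) or np.any(row > 1 + _TOL):
        raise ValueError(f"patient {pid}: DVH values outside [0, 1]")
    if np.any(np.diff(row) > _TOL):
        raise ValueError(f"patient {pid}: DVH row is not non-increasing")
    if abs(grid.d_min) < _TOL and abs(row[0] - 1.0) > _TOL:
        raise ValueError(f"patient {pid}: DVH at d=0 must equal 1")


def _dose_label(d: float) -> str:
    return f"V_{d:.2f}"


def write_cohort(cohort: Cohort, dvh_csv_path, clinical_csv_path) -> None:
    """Write a cohort as two CSVs (wide DVH table + clinical table)."""
    # default float formatting is the shortest round-trip repr
    dvh = pd.DataFrame(cohort.volumes, columns=[_dose_label(d) for d in cohort.grid.points])
    dvh.insert(0, "patient_id", cohort.patient_ids)
    dvh.to_csv(dvh_csv_path, index=False)
    cohort.clinical_frame().to_csv(clinical_csv_path, index=False)


def read_cohort(dvh_csv_path, clinical_csv_path) -> Cohort:
    """Read a cohort from the two-CSV layout written by :func:`write_cohort`."""
    dvh = pd.read_csv(dvh_csv_path, float_precision="round_trip")
    clin = pd.read_csv(clinical_csv_path, float_precision="round_trip")
    if "patient_id" not in dvh.columns or "patient_id" not in clin.columns:
        raise ValueError("both CSVs must contain a patient_id column")
    if "outcome" not in clin.columns:
        raise ValueError("clinical CSV is missing the outcome column")
    dose_cols = [c for c in dvh.columns if c.startswith("V_")]
    if not dose_cols:
        raise ValueError("DVH CSV has no dose columns (expected V_<dose> headers)")
    doses = np.array([float(c[2:]) for c in dose_cols])
    order = np.argsort(doses)
    doses = doses[order]
    dose_cols = [dose_cols[i] for i in order]
    steps = np.diff(doses)
    if doses.size > 1 and not np.allclose(steps, steps[0], atol=1e-6):
        raise ValueError("DVH dose columns are not uniformly spaced")
    step = float(steps[0]) if doses.size > 1 else 1.0
    grid = build_dose_grid(float(doses[0]), float(doses[-1]), step)

    dvh_ids = [str(p) for p in dvh["patient_id"]]
    clin_ids = [str(p) for p in clin["patient_id"]]
    if dvh_ids != clin_ids:
        raise ValueError("patient_id columns of the DVH and clinical CSVs do not match")

    volumes = dvh[dose_cols].to_numpy(dtype=float)
    for pid, row in zip(dvh_ids, volumes):
        _validate_dvh_row(pid, row, grid)

    clinical = [
        ClinicalCovariates(
            sex=str(r.sex),
            age=float(r.age),
            rt_intent=str(r.rt_intent),
            induction_chemo=str(r.induction_chemo),
            concurrent_chemo=str(r.concurrent_chemo),
            primary_site=str(r.primary_site),
        )
        for r in clin.itertuples()
    ]
    return Cohort(
        patient_ids=dvh_ids,
        grid=grid,
        volumes=volumes,
        clinical=clinical,
        outcome=clin["outcome"].to_numpy(dtype=int),
    )
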