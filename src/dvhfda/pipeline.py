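"""Orchestration: simulate -> fit -> validate with one master seed.

Every stochastic stage consumes a seed derived from the master seed via
a named substream scheme (``simulate``/``fit``/``bootstrap``/``orci``),
so e.g. changing the bootstrap replicate count does not perturb the
simulated cohort.  All artifacts are plain text (CSV/JSON) and contain
no timestamps, so a fixed configuration reproduces byte-identical
output.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .dvh import Cohort, write_cohort
from .plr import plr_model_to_json
from .recipes import FunctionalLRRecipe, PLRRecipe
from .regression import model_to_json
from .simulate import generate_cohort, preset_dysphagia_like, preset_mucositis_like
from .validation import bootstrap_or_ci, optimism_correct

__all__ = ["RunConfig", "run_pipeline", "derive_seed", "recipe_for"]

_SUBSTREAMS = {"simulate": 0, "fit": 1, "bootstrap": 2, "orci": 3}

METHODS = ("plr", "fpc-lr", "fpls-lr")
PRESETS = ("mucositis", "dysphagia")


def derive_seed(master_seed: int, role: str) -> int:
    """Stable per-role seed below 2**31, derived from one master seed."""
    if role not in _SUBSTREAMS:
        raise ValueError(f"unknown seed role {role!r}")
    ss = np.random.SeedSequence([int(master_seed), _SUBSTREAMS[role]])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


@dataclass
class RunConfig:
    """Configuration of one end-to-end run."""

    method: str = "fpls-lr"
    preset: str = "mucositis"
    n_patients: int = 200
    component_budget: int = 5
    r_grid: Optional[list] = None  # None -> default grid
    folds: int = 10
    lambda_path_size: int = 100
    bootstrap_replicates: int = 200
    master_seed: int = 0
    outdir: str = "dvhfda_run"

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}, got {self.method!r}")
        if self.preset not in PRESETS:
            raise ValueError(f"preset must be one of {PRESETS}, got {self.preset!r}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


def recipe_for(config: RunConfig):
    if config.method == "plr":
        return PLRRecipe(folds=config.folds, path_size=config.lambda_path_size)
    kind = "fpca" if config.method == "fpc-lr" else "fpls"
    r_grid = None if config.r_grid is None else np.asarray(config.r_grid, dtype=float)
    kwargs = {} if r_grid is None else {"r_grid": r_grid}
    return FunctionalLRRecipe(kind=kind, component_budget=config.component_budget, **kwargs)


def _simulate(config: RunConfig):
    preset = preset_mucositis_like if config.preset == "mucositis" else preset_dysphagia_like
    sim = preset(n_patients=config.n_patients, seed=derive_seed(config.master_seed, "simulate"))
    return generate_cohort(sim)


def _write_truth(truth, cohort: Cohort, path) -> None:
    rows = [("beta", f"{d:.2f}", v) for d, v in zip(cohort.grid.points, truth.true_beta)]
    rows += [("intercept", "intercept", truth.true_intercept)]
    rows += [
        ("clinical_coefficient", name, v)
        for name, v in zip(cohort.design().column_names, truth.true_clinical_coefficients)
    ]
    rows += [
        ("linear_predictor", pid, v)
        for pid, v in zip(cohort.patient_ids, truth.linear_predictor)
    ]
    pd.DataFrame(rows, columns=["kind", "name", "value"]).to_csv(
        path, index=False, float_format="%.17g"
    )


def _report_payload(report) -> dict:
    return {
        "B": report.B,
        "n_redrawn": report.n_redrawn,
        "apparent": report.apparent,
        "optimism": report.optimism,
        "corrected": report.corrected,
    }


def run_pipeline(config: RunConfig) -> dict:
    """simulate -> fit -> validate -> orci; returns the artifact paths."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {name: outdir / fname for name, fname in {
        "dvh": "dvh.csv",
        "clinical": "clinical.csv",
        "truth": "truth.csv",
        "model": "model.json",
        "report": "report.json",
        "replicates": "replicates.csv",
        "or_table": "or_table.csv",
        "manifest": "manifest.json",
    }.items()}

    cohort, truth = _simulate(config)
    write_cohort(cohort, paths["dvh"], paths["clinical"])
    _write_truth(truth, cohort, paths["truth"])

    recipe = recipe_for(config)
    fit_rng = np.random.default_rng(derive_seed(config.master_seed, "fit"))
    fitted = recipe.fit(cohort, fit_rng)
    if config.method == "plr":
        paths["model"].write_text(plr_model_to_json(fitted.model))
    else:
        paths["model"].write_text(model_to_json(fitted.model, fitted.selection))

    report = optimism_correct(
        recipe, cohort, B=config.bootstrap_replicates,
        seed=derive_seed(config.master_seed, "bootstrap"),
    )
    paths["report"].write_text(json.dumps(_report_payload(report), indent=2, sort_keys=True))
    report.replicates.to_csv(paths["replicates"], index=False, float_format="%.17g")

    or_table = bootstrap_or_ci(
        recipe, cohort, B=config.bootstrap_replicates,
        seed=derive_seed(config.master_seed, "orci"),
    )
    or_table.to_csv(paths["or_table"], index=False, float_format="%.17g")

    try:
        pkg_version = version("dvhfda")
    except PackageNotFoundError:
        pkg_version = "unknown"
    manifest = {
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "package_version": pkg_version,
        "artifacts": {k: p.name for k, p in paths.items() if k != "manifest"},
    }
    paths["manifest"].write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return {k: str(p) for k, p in paths.items()}
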