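import numpy as np
import pytest

import dvhfda as d


@pytest.fixture(scope="session")
def fda_grid():
    return d.build_dose_grid(0.0, 2.60, 0.01)


@pytest.fixture(scope="session")
def plr_grid():
    return d.build_dose_grid(0.2, 2.6, 0.2)


@pytest.fixture(scope="session")
def small_cohort():
    """300-patient mucositis-like cohort with ground truth."""
    cohort, truth = d.generate_cohort(d.preset_mucositis_like(n_patients=300, seed=42))
    return cohort, truth


@pytest.fixture(scope="session")
def tiny_cohort():
    """Fast 60-patient cohort for plumbing tests."""
    cohort, truth = d.generate_cohort(d.preset_dysphagia_like(n_patients=60, seed=7))
    return cohort, truth


def quadrature_cosine(a, b, step):
    num = step * float(np.dot(a, b))
    return num / np.sqrt((step * float(a @ a)) * (step * float(b @ b)))
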