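# dvhfda

Functional data analysis of dose-volume histograms (DVHs) for normal
tissue complication probability (NTCP) modeling.

## Who this is for

Radiotherapy outcomes researchers modeling binary toxicity endpoints
(e.g. severe acute mucositis or dysphagia in head-and-neck RT) from
organ-at-risk dose distributions. Adjacent DVH dose levels are almost
perfectly correlated, so ordinary or LASSO logistic regression on
sampled DVH points yields unstable, hard-to-interpret coefficients.
This package treats each patient's normalized cumulative fractional-dose
DVH, V(d), as one functional observation and fits

  logit P(y = 1) = α + Σⱼ βⱼ Zⱼ + ∫ β(d) V(d) dd,

where Z are clinical covariates and β(d) — the dose-weighting function,
the quantity of scientific interest — is expanded in data-driven
components: unsupervised FPCA eigenfunctions or supervised FPLS
components (maximal squared covariance with the outcome, mutually
orthogonal). Curvature of β(d) is penalized (roughness penalty r on
the integrated squared second derivative), and the component count and
r are chosen by a BIC-style criterion (MSC). A LASSO logistic
comparator on 13 sampled Vx points, bootstrap optimism-corrected
internal validation (AUC, Brier, calibration slope/intercept) and
percentile bootstrap odds-ratio intervals complete the workflow. Since
the originating patient data are not public, a synthetic DVH cohort
generator with known ground truth (known β*, known clinical effects)
drives all studies and tests.

## Worked example

```python
import numpy as np
import dvhfda as d

# a 300-patient mucositis-like cohort with known ground truth
cohort, truth = d.generate_cohort(d.preset_mucositis_like(n_patients=300, seed=42))
print(f"prevalence: {cohort.outcome.mean():.2f}")

# FPCA: how much curve variance do the leading components carry?
basis = d.fpca_decompose(cohort)
print("variance explained (%):", np.round(d.variance_explained(basis, 5), 1))

# FPLS-LR with MSC selection of (components, penalty)
sel = d.msc_select(cohort.volumes, cohort.outcome.astype(float),
                   cohort.design(), basis_kind="fpls", grid=cohort.grid)
print(f"selected k={sel.k_n}, r={sel.r:g}")

# how well is the true dose weighting recovered?
bhat, bstar, step = sel.model.beta_function, truth.true_beta, cohort.grid.step
cos = step * bhat @ bstar / np.sqrt((step * bhat @ bhat) * (step * bstar @ bstar))
print(f"cosine(beta_hat, beta_star) = {cos:.2f}")
```

Output:

```
prevalence: 0.77
variance explained (%): [73.2 16.8  5.4  2.3  1.1]
selected k=1, r=0
cosine(beta_hat, beta_star) = 0.90
```

The first component carries ~73% of the between-patient DVH variance;
model selection keeps a single supervised component, and the fitted
weighting function points in nearly the same direction as the true
monotone dose weighting (quadrature cosine 0.90 at n=300).

Internal validation with the full recipe re-tuned on every bootstrap
resample:

```python
recipe = d.FunctionalLRRecipe(kind="fpls", component_budget=3)
report = d.optimism_correct(recipe, cohort, B=200, seed=0)
print(report.as_frame())
```

A thin CLI mirrors the library: `dvhfda simulate | fit | validate |
orci | run` (see `dvhfda --help`); `examples/` contains one short
narrative script per capability.

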