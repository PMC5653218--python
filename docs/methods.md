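# Methods

## Problem and model

Normal tissue complication probability (NTCP) models relate the
radiation dose received by an organ at risk to the probability of a
toxicity event. The dose input is the normalized cumulative
dose-volume histogram (DVH) of the *fractional* dose distribution:
V(d) = fraction of the organ receiving at least d Gy per fraction,
evaluated on a shared uniform grid (0–2.60 Gy at 0.01 Gy; 261 points).
Adjacent dose levels of a DVH are almost perfectly correlated, which
makes per-dose-level logistic regression coefficients unstable; the
package instead treats each DVH as a single functional observation.

Two data-driven dimension reductions are provided:

- **FPCA** — eigenfunctions ξ_k(d) of the curve covariance operator
  Σ(d₁,d₂) = Cov[V(d₁),V(d₂)] under the left-Riemann quadrature inner
  product ⟨f,g⟩ = Δd Σ f(d_k)g(d_k). Computed via SVD of the centered
  curve matrix; eigenvalues use divisor n (expectation convention).
- **FPLS** — NIPALS-style PLS1 components for a single centered binary
  response: the first component is the normalized cross-covariance
  function w(d) ∝ Cov(V(d), y), which maximizes the squared covariance
  of the projected curves with the outcome among unit-quadrature-norm
  directions; later components repeat the construction on rank-1
  deflated curves with explicit Gram–Schmidt re-orthogonalization.

Both yield orthonormal components, per-patient projection scores
c_ik = ⟨V_i − μ, ξ_k⟩, and a functional logistic regression

  logit P(y_i = 1) = α + Σ_j β_j Z_j + Σ_k β_k c_ik,

with clinical covariates Z (sex, age, RT intent, induction chemo,
concurrent chemo regimen, primary-site group; dummy coding with
oropharynx/oral-cavity and no-concurrent-chemo as reference levels).
The implied dose-weighting function is β(d) = Σ_k β_k ξ_k(d).

A note on score correlation: projection scores of *orthonormal*
components are generally correlated on collinear functional data (the
covariance operator does not commute with the projection). We keep the
projection-score definition because it is what makes β(d) = Σ β_k ξ_k
exactly consistent with the score-space linear predictor; the fits
remain well conditioned and a collinearity guard rejects degenerate
designs.

## Penalized fitting and model selection

Fitting is maximum penalized likelihood by IRLS: the Bernoulli
log-likelihood minus (r/2)·β_fᵀRβ_f, where R_jk = Δd Σ ξ_j''(d)ξ_k''(d)
is the curvature Gram matrix of the components (second-order central
differences, one-sided at the grid ends) and the penalty acts on the
functional coefficients only — clinical coefficients are never
penalized. Convergence: max coefficient change < 1e-8 or 100
iterations. Perfect separation is detected (fitted logits at the ±30
clip bound) and flagged `converged=False` with finite coefficients.
Dummy columns that are all zero in a given cohort or bootstrap resample
(an absent category) are dropped from the fit and reported with
coefficient 0, i.e. odds ratio exactly 1.

The component count k_n (leading prefixes of the first 5) and penalty r
(grid {0} ∪ 15 log-spaced values in [0.1, 1350]) are selected by a
BIC-style criterion on the probability scale:

  MSC = log[(1/n) Σ (y_i − ŷ_i)²] + log(n) · df / (n/2),

where df is the **effective degrees of freedom** of the penalized
functional block, tr[(XᵀWX+P)⁻¹XᵀWX] minus the unpenalized column
count. At r = 0, df equals k_n exactly, recovering the raw-count form
of the criterion; as r grows, df shrinks toward the dimension of the
curvature-free subspace. This choice is deliberate: with a raw count
the criterion is monotone in r and heavy smoothing could never be
selected, whereas with effective df a large penalty wins whenever the
curvature it removes buys more complexity credit than it costs in fit —
on pure-noise outcomes the modal selection is one component at the
strongest penalty. The raw count remains available
(`msc_complexity="component_count"`), as does the alternative
denominator n (`msc_denominator="n"`). Ties break to the smaller k_n,
then the larger r.

## The LASSO comparator

The non-functional baseline samples each DVH at 13 points (0.2–2.6 Gy
at 0.2 Gy; Vx in percent volume, so odds ratios are per percent) and
fits an L1-penalized logistic regression on the 13 Vx plus 11 clinical
columns. λ is chosen by stratified 10-fold cross-validation maximizing
mean out-of-fold AUC (ties → larger λ); the path is 100 log-spaced
values from the smallest all-slopes-zero λ down four decades. Slopes
are fit by liblinear on standardized columns with the intercept
unpenalized (large intercept scaling plus an exact damped-Newton
intercept refit at fixed slopes); coefficients are reported on the
original scale, and exact zeros render as odds ratio 1.000. λ = 0
falls back to the unpenalized MLE.

## Validation

- AUC: Mann–Whitney (ties 1/2). Brier: mean squared error on the
  probability scale. Calibration: logistic regression of outcomes on
  logit(p) (p clipped to [1e-8, 1−1e-8]); slope and intercept from the
  same two-parameter fit by default, the fixed-slope
  (calibration-in-the-large) intercept behind a flag; slope < 1 means
  overfitting, > 1 underfitting.
- Internal validation uses the Efron optimism bootstrap: the *entire*
  recipe — component extraction, MSC or CV tuning, fitting — is re-run
  on each plain (unstratified) resample; optimism is the mean of
  (metric on the resample − metric of that model on the original data),
  and corrected = apparent − optimism, applied additively to all four
  metrics. Single-class resamples are redrawn (capped at 2B).
- Odds-ratio uncertainty: percentile 2.5/97.5 of exp(coefficient) over
  B replicates of the full recipe; covariates absent from a replicate's
  selected model contribute OR = 1. The paper-scale default is
  B = 2000; desk-scale runs and all tests use B ≤ 200, which the
  replicate-count field of every report records.

## Synthetic cohorts (what the generator does and does not emulate)

No patient data are distributed with the package; all studies run on a
generator that emulates the statistical structure the method assumes:

- Curves are two sigmoidal shoulders at the fractional prescription
  levels (1.8 and 2.1 Gy/fraction), mixed by a Beta(2,2) target-overlap
  fraction, with shoulder width 0.10 Gy (lognormal jitter σ = 0.3),
  center jitter SD 0.30 Gy (low shoulder — pooled trials prescribe
  different fractional doses) and 0.12 Gy (high shoulder — hot-spot
  scale), plus smooth sinusoidal idiosyncratic variation of amplitude
  0.05 vanishing at d = 0. Curves are repaired to be bounded,
  non-increasing, and equal to 1 at zero dose. This reproduces the
  qualitative covariance structure of clinical DVH cohorts (adjacent
  correlations > 0.95, variance concentrated near the prescription
  levels, several smooth variance modes), not the aesthetics of any
  particular planning system.
- Outcomes follow the functional logistic model with true weighting
  β*(d) = 3·expit((d−1.0)/0.25)·expit((2.45−d)/0.08) — a monotone ramp
  putting the weight on doses above ~1 Gy/fraction, tapering to zero
  over the last ~0.2 Gy of the grid, beyond the maximum dose any tissue
  receives. The taper keeps the recovery estimand well defined: no
  estimator has information at dose levels never delivered. True
  clinical log-odds put a strong cisplatin effect (1.4) and an exactly
  null induction-chemotherapy effect, so both power and coverage of the
  bootstrap intervals can be exercised. Preset intercepts are found by
  root-finding so cohort-average risk hits the target prevalences
  (0.73 mucositis-like, 0.66 dysphagia-like).
- Clinical covariate marginals are plausible head-and-neck trial values
  chosen here (the source cohorts' joint distribution is not public);
  covariate–dose correlations (e.g. parotid primaries receiving less
  mucosal dose) are not emulated. Passing tests therefore demonstrate
  the machinery's statistical correctness under the assumed curve and
  outcome model, not performance on any clinical dataset.

## Problem sizes used by the test suite and acceptance script

Oracle equivalences run at n = 20–300 on the full 261-point grid.
Parameter recovery uses 20 cohorts of n = 1000 (3 FPLS components,
penalty selected by MSC); the reported quantity is the median
quadrature cosine between β̂(d) and β*(d). Optimism behavior uses 20
runs at n = 100, B = 200 with a deliberately overfit 50-noise-covariate
logistic recipe; OR coverage uses 200 outer cohorts of n = 500 with
B = 200 each; the end-to-end determinism check runs the full pipeline
twice at n = 150, B = 50. The acceptance script mirrors these at
B = 100 / 10 recovery cohorts and reports each quantity with the
problem size it used.

## Known limitations

- β(d) is estimable only where curves vary; at dose levels with no
  between-patient variance the fitted weighting is pulled to zero, a
  property inherited from any data-driven basis.
- The percentile bootstrap can be mildly conservative for coefficients
  of rare categories; BCa intervals are out of scope.
- The optimism correction is applied additively to calibration slope
  and intercept as to AUC and Brier; for strongly underfit models an
  additive slope correction can overshoot.
- The MSC effective-df generalization reduces to the raw-count
  criterion at r = 0 but is not the only possible reading of the
  criterion's complexity term; both variants are exposed.
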