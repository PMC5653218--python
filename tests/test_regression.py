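"""Functional logistic regression: penalty, IRLS, MSC selection, prediction."""

import numpy as np
import pytest
from scipy.special import expit

import dvhfda as d
from dvhfda.fpls import fpls_decompose
from dvhfda.regression import (
    bernoulli_loglik,
    fit_functional_logistic,
    model_from_json,
    model_to_json,
    msc_select,
    msc_value,
    penalty_matrix,
    second_derivatives,
)


@pytest.fixture(scope="module")
def fitted_setup(small_cohort):
    cohort, _ = small_cohort
    y = cohort.outcome.astype(float)
    basis = fpls_decompose(cohort.volumes, y, k_max=3, grid=cohort.grid)
    return cohort, y, basis


class TestPenaltyMatrix:
    def test_linear_component_zero_row(self):
        g = d.build_dose_grid(0.0, 1.0, 0.1)
        comps = np.stack([0.3 * g.points + 0.1, np.sin(3 * g.points)])
        from dvhfda.fpca import FunctionalBasis

        basis = FunctionalBasis(
            grid=g, kind="fpca", components=comps, eigenvalues=np.ones(2),
            mean_function=np.zeros(g.size), scores=np.zeros((2, 2)), total_variance=1.0,
        )
        R = penalty_matrix(basis)
        np.testing.assert_allclose(R[0], 0.0, atol=1e-10)
        np.testing.assert_allclose(R[:, 0], 0.0, atol=1e-10)
        assert R[1, 1] > 0

    def test_pure_quadratic_hand_value(self):
        # xi(d) = d^2 on a unit-step grid: second differences are exactly 2
        # everywhere (the one-sided boundary scheme is exact for quadratics),
        # so R = dd * sum(2*2) = 4 * step * count.
        g = d.build_dose_grid(0.0, 9.0, 1.0)
        dd = second_derivatives((g.points**2)[None, :], g.step)
        np.testing.assert_allclose(dd, 2.0)
        R = g.step * dd @ dd.T
        assert R[0, 0] == pytest.approx(4.0 * g.step * g.size)

    def test_symmetry_and_psd(self, fitted_setup):
        _, _, basis = fitted_setup
        R = penalty_matrix(basis)
        np.testing.assert_array_equal(R, R.T)
        assert np.linalg.eigvalsh(R).min() > -1e-10

    def test_short_grid_rejected(self):
        with pytest.raises(ValueError):
            second_derivatives(np.ones((1, 2)), 1.0)


class TestFit:
    def test_unpenalized_matches_statsmodels_oracle(self, fitted_setup):
        import statsmodels.api as sm

        cohort, y, basis = fitted_setup
        design = cohort.design()
        model = fit_functional_logistic(basis.scores, design, y, r=0.0)
        X = sm.add_constant(np.column_stack([basis.scores, design.values]))
        oracle = sm.GLM(y, X, family=sm.families.Binomial()).fit(tol=1e-12)
        ours = np.concatenate(
            [[model.intercept], model.functional_coefficients, model.clinical_coefficients]
        )
        np.testing.assert_allclose(ours, oracle.params, atol=1e-6)

    def test_huge_penalty_kills_curvature(self, fitted_setup):
        cohort, y, basis = fitted_setup
        R = penalty_matrix(basis, 3)
        m0 = fit_functional_logistic(basis.scores, None, y, r=0.0, penalty=R, basis=basis)
        m9 = fit_functional_logistic(basis.scores, None, y, r=1e9, penalty=R, basis=basis)
        q0 = m0.functional_coefficients @ R @ m0.functional_coefficients
        q9 = m9.functional_coefficients @ R @ m9.functional_coefficients
        assert q9 < 1e-6 * q0

    def test_effective_df_bounds(self, fitted_setup):
        cohort, y, basis = fitted_setup
        R = penalty_matrix(basis, 3)
        m0 = fit_functional_logistic(basis.scores, None, y, r=0.0, penalty=R, basis=basis)
        assert m0.edf_functional == pytest.approx(3.0, abs=1e-6)
        m = fit_functional_logistic(basis.scores, None, y, r=100.0, penalty=R, basis=basis)
        assert 0.0 <= m.edf_functional < 3.0

    def test_single_class_rejected(self, fitted_setup):
        cohort, y, basis = fitted_setup
        with pytest.raises(ValueError):
            fit_functional_logistic(basis.scores, None, np.ones_like(y))

    def test_collinearity_rejected_with_names(self, fitted_setup):
        cohort, y, basis = fitted_setup
        scores = np.column_stack([basis.scores[:, 0], basis.scores[:, 0]])
        with pytest.raises(ValueError, match="collinear"):
            fit_functional_logistic(scores, None, y)

    def test_separation_flagged_not_crashed(self):
        rng = np.random.default_rng(0)
        s = rng.standard_normal(40)[:, None]
        y = (s[:, 0] > 0).astype(float)
        model = fit_functional_logistic(s, None, y)
        assert not model.converged
        assert np.all(np.isfinite(model.functional_coefficients))

    def test_local_optimum_spot_check(self, fitted_setup):
        """No random perturbation of the r=0 solution improves the log-likelihood."""
        cohort, y, basis = fitted_setup
        design = cohort.design()
        model = fit_functional_logistic(basis.scores, design, y, r=0.0)
        X = np.column_stack([np.ones(cohort.n), basis.scores, design.values])
        beta = np.concatenate(
            [[model.intercept], model.functional_coefficients, model.clinical_coefficients]
        )
        ll_hat = bernoulli_loglik(y, X @ beta)
        rng = np.random.default_rng(3)
        for _ in range(100):
            pert = beta + rng.normal(0, 0.05, beta.shape)
            assert bernoulli_loglik(y, X @ pert) <= ll_hat + 1e-10

    def test_nested_loglik_never_decreases(self, fitted_setup):
        cohort, y, basis = fitted_setup
        design = cohort.design()
        lls = []
        for k in (1, 2, 3):
            m = fit_functional_logistic(basis.scores[:, :k], design, y, r=0.0)
            eta = m.linear_predictor(basis.scores[:, :k], design.values)
            lls.append(bernoulli_loglik(y, eta))
        assert lls[0] <= lls[1] + 1e-9 <= lls[2] + 2e-9


class TestBetaFunction:
    def test_zero_coefficients_zero_function(self, fitted_setup):
        _, _, basis = fitted_setup
        m = d.FittedModel(
            intercept=0.0, clinical_coefficients=np.zeros(0), clinical_names=(),
            functional_coefficients=np.zeros(3), basis=basis, k_n=3, r=0.0,
            converged=True, n_iterations=0,
        )
        np.testing.assert_array_equal(m.beta_function, np.zeros(basis.grid.size))

    def test_single_component_scaling(self, fitted_setup):
        _, _, basis = fitted_setup
        m = d.FittedModel(
            intercept=0.0, clinical_coefficients=np.zeros(0), clinical_names=(),
            functional_coefficients=np.array([2.0]), basis=basis, k_n=1, r=0.0,
            converged=True, n_iterations=0,
        )
        np.testing.assert_allclose(m.beta_function, 2.0 * basis.components[0])

    def test_quadrature_of_beta_reproduces_linear_predictor(self, fitted_setup):
        """alpha + Z b + dd*sum(beta(d) (V - mu)) equals the score-space predictor."""
        cohort, y, basis = fitted_setup
        design = cohort.design()
        model = fit_functional_logistic(basis.scores, design, y, r=0.0, basis=basis)
        eta_scores = model.linear_predictor(basis.scores, design.values)
        bf = model.beta_function
        centered = cohort.volumes - basis.mean_function
        eta_quad = (
            model.intercept
            + design.values @ model.clinical_coefficients
            + cohort.grid.step * centered @ bf
        )
        np.testing.assert_allclose(eta_scores, eta_quad, atol=1e-8)


class TestMSC:
    def test_identical_fit_prefers_fewer_components(self):
        y = np.array([0, 1, 0, 1, 1.0])
        p = np.array([0.3, 0.6, 0.4, 0.7, 0.5])
        assert msc_value(y, p, 1.0) < msc_value(y, p, 2.0)

    def test_matches_hand_evaluated_toy_grid(self, fitted_setup):
        """Selector table equals a by-hand evaluation of the criterion."""
        cohort, y, basis = fitted_setup
        design = cohort.design()
        sel = msc_select(
            cohort.volumes, y, design, basis_kind="fpls", component_budget=3,
            r_grid=[0.0], grid=cohort.grid, basis=basis,
        )
        n = cohort.n
        for _, row in sel.candidates.iterrows():
            k = int(row.k_n)
            m = fit_functional_logistic(basis.scores[:, :k], design, y, r=0.0)
            p_hat = expit(m.linear_predictor(basis.scores[:, :k], design.values))
            by_hand = np.log(np.mean((y - p_hat) ** 2)) + np.log(n) * k / (n / 2)
            assert row.msc == pytest.approx(by_hand, abs=1e-12)
        best = sel.candidates.loc[sel.candidates.msc.idxmin()]
        assert sel.k_n == int(best.k_n)

    def test_tie_breaks_to_smaller_k_then_larger_r(self):
        import pandas as pd

        # construct a selector-shaped table and reuse the selection rule
        from dvhfda.regression import SelectionResult  # noqa: F401

        table = pd.DataFrame(
            {"k_n": [1, 1, 2], "r": [0.0, 10.0, 0.0], "msc": [-1.0, -1.0, -1.0]}
        )
        best = table["msc"].min()
        near = table[table["msc"] <= best + 1e-12]
        k_sel = int(near["k_n"].min())
        r_sel = float(near[near["k_n"] == k_sel]["r"].max())
        assert (k_sel, r_sel) == (1, 10.0)

    def test_pure_noise_selects_one_heavily_penalized_component(self):
        """Permuted outcomes: the modal selection is k=1 with a large penalty."""
        ks, rs = [], []
        for seed in range(10):
            cohort, _ = d.generate_cohort(d.preset_mucositis_like(n_patients=200, seed=300 + seed))
            rng = np.random.default_rng(seed)
            y = rng.permutation(cohort.outcome).astype(float)
            sel = msc_select(cohort.volumes, y, cohort.design(), "fpls", 5, grid=cohort.grid)
            ks.append(sel.k_n)
            rs.append(sel.r)
        from collections import Counter

        assert Counter(ks).most_common(1)[0][0] == 1
        assert np.median(rs) >= 100.0


class TestPredict:
    def test_training_predictions_in_unit_interval(self, fitted_setup, small_cohort):
        cohort, y, basis = fitted_setup
        model = fit_functional_logistic(basis.scores, cohort.design(), y, basis=basis)
        p = d.predict(model, cohort)
        assert np.all((p > 0) & (p < 1))

    def test_manual_linear_predictor_for_three_patients(self, fitted_setup):
        cohort, y, basis = fitted_setup
        design = cohort.design()
        model = fit_functional_logistic(basis.scores, design, y, basis=basis)
        p = d.predict(model, cohort)
        for i in (0, 5, 17):
            eta = (
                model.intercept
                + basis.scores[i] @ model.functional_coefficients
                + design.values[i] @ model.clinical_coefficients
            )
            assert p[i] == pytest.approx(expit(eta), abs=1e-10)

    def test_pointwise_larger_dvh_gets_larger_probability(self):
        """With beta(d) >= 0 and no clinical effects, dominance in dose
        implies dominance in predicted risk."""
        g = d.build_dose_grid(0.0, 2.0, 0.1)
        rng = np.random.default_rng(5)
        base = expit((1.4 - g.points) / 0.3)
        X = []
        for i in range(60):
            v = np.clip(base + rng.normal(0, 0.05) * np.sin(np.pi * g.points / 2), 0, 1)
            v[0] = 1
            X.append(np.minimum.accumulate(v))
        X = np.stack(X)
        y = rng.integers(0, 2, 60).astype(float)
        basis = fpls_decompose(X, y, k_max=1, grid=g)
        model = fit_functional_logistic(basis.scores, None, y, basis=basis)
        bf = model.beta_function
        lo = np.clip(base - 0.1, 0, 1); lo[0] = 1
        hi = np.clip(base + 0.1, 0, 1); hi[0] = 1
        if np.all(bf >= 0):
            s_lo, s_hi = (g.step * (c - basis.mean_function) @ bf for c in (lo, hi))
            assert s_hi >= s_lo

    def test_grid_mismatch_rejected(self, fitted_setup, small_cohort):
        cohort, y, basis = fitted_setup
        model = fit_functional_logistic(basis.scores, cohort.design(), y, basis=basis)
        other, _ = d.generate_cohort(
            d.SimulationConfig(n_patients=10, grid=d.build_dose_grid(0.0, 2.6, 0.2), seed=0)
        )
        with pytest.raises(ValueError, match="grid"):
            d.predict(model, other)


class TestSerialization:
    def test_round_trip(self, fitted_setup, small_cohort):
        cohort, y, basis = fitted_setup
        model = fit_functional_logistic(basis.scores, cohort.design(), y, basis=basis)
        back = model_from_json(model_to_json(model))
        p0 = d.predict(model, cohort)
        p1 = d.predict(back, cohort)
        np.testing.assert_allclose(p0, p1, atol=1e-12)
        assert back.k_n == model.k_n and back.r == model.r
        np.testing.assert_allclose(back.functional_coefficients, model.functional_coefficients)
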