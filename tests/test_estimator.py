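"""Intrinsic-estimator fit: deviance, information criteria, and oracle checks."""

import numpy as np
import pytest
import scipy.linalg
import scipy.optimize

from apcie import (
    DesignSpec,
    SimConfig,
    ValidationError,
    build_design,
    deviance,
    fit_ie,
    information_criteria,
    null_vector,
    poisson_log_likelihood,
    simulate,
)
from conftest import make_table


class TestDeviance:
    def test_saturated_fit_has_zero_deviance(self):
        d = np.array([3.0, 7.0, 1.0])
        assert deviance(d, d) == 0.0

    def test_zero_count_contributes_twice_the_fitted_mean(self):
        assert deviance(np.array([0.0]), np.array([2.0])) == pytest.approx(4.0)

    def test_hand_computed_value(self):
        # 2 * (3 ln 1.5 - 1)
        assert deviance(np.array([3.0]), np.array([2.0])) == pytest.approx(0.4327906, abs=1e-6)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValidationError):
            deviance(np.array([-1.0]), np.array([1.0]))


class TestInformationCriteria:
    def test_bic_convention_reproduces_published_value(self):
        # deviance 1.246, 78 cells, 34 estimable directions
        _, bic = information_criteria(1.246, 0.0, 78, 34)
        assert bic == pytest.approx(-190.449, abs=5e-4)

    def test_bic_closed_forms(self):
        _, bic = information_criteria(0.0, 0.0, 10, 9)
        assert bic == pytest.approx(-np.log(10))
        _, bic = information_criteria(3.7, 0.0, 1, 0)
        assert bic == pytest.approx(3.7)

    def test_aic_per_observation(self):
        aic, _ = information_criteria(0.0, -100.0, 50, 34)
        assert aic == pytest.approx((200.0 + 2 * 35) / 50)

    def test_rank_must_be_below_n(self):
        with pytest.raises(ValidationError):
            information_criteria(1.0, 0.0, 34, 34)


class TestFitIE:
    def test_null_structure_recovery(self):
        cfg = SimConfig(n_age=5, n_period=4, population=1e9,
                        effect_scale=0.0, intercept=np.log(1e-4), seed=3)
        table, _ = simulate(cfg)
        fit = fit_ie(table)
        assert np.abs(fit.age_effects).max() < 0.01
        assert np.abs(fit.period_effects).max() < 0.01
        assert np.abs(fit.cohort_effects).max() < 0.01
        assert fit.intercept == pytest.approx(np.log(1e-4), abs=0.01)

    def test_fit_invariants(self, study_table_modeled):
        fit = fit_ie(study_table_modeled)
        assert fit.converged
        assert abs(fit.age_effects.sum()) < 1e-8
        assert abs(fit.period_effects.sum()) < 1e-8
        assert abs(fit.cohort_effects.sum()) < 1e-8
        assert abs(fit.theta @ fit.b0_used) < 1e-8
        observed = study_table_modeled.deaths.sum()
        assert fit.fitted_deaths.sum() == pytest.approx(observed, rel=1e-6)
        assert fit.n_obs == 78 and fit.model_rank == 34

    def test_effects_frame_has_37_rows_for_study_grid(self, study_table_modeled):
        frame = fit_ie(study_table_modeled).effects_frame()
        assert len(frame) == 37
        assert frame["dimension"].value_counts().to_dict() == {
            "cohort": 18, "age": 13, "period": 6,
        }

    def test_annual_spacing_rejected(self, study_sim):
        table, _ = study_sim  # 26 annual periods: diagonals are not 5-year cohorts
        with pytest.raises(ValidationError, match="spaced 5 years"):
            fit_ie(table)

    def test_matches_penalized_likelihood_oracle_on_3x3(self):
        # Brute force: maximise the Poisson likelihood with a heavy quadratic
        # penalty on the null-direction component; the optimum approaches the
        # IE solution as the penalty weight grows.
        deaths = np.array([[4.0, 6.0, 3.0], [5.0, 2.0, 7.0], [8.0, 4.0, 6.0]])
        table = make_table(deaths, 1e5)
        fit = fit_ie(table)
        X = build_design(DesignSpec(3, 3)).values
        b0 = null_vector(build_design(DesignSpec(3, 3)))
        y = table.deaths.reshape(-1)
        offset = np.log(table.population.reshape(-1))
        lam = 1e7

        def objective(theta):
            eta = offset + X @ theta
            mu = np.exp(eta)
            grad = X.T @ (mu - y) + 2 * lam * (theta @ b0) * b0
            return float(np.sum(mu - y * eta)) + lam * (theta @ b0) ** 2, grad

        res = scipy.optimize.minimize(
            objective, np.zeros(X.shape[1]), jac=True, method="BFGS",
            options={"gtol": 1e-12, "maxiter": 2000},
        )
        assert np.abs(res.x - fit.theta).max() < 1e-5

    def test_matches_pseudoinverse_of_converged_irls_system(self, study_table_modeled):
        # At convergence the IE coefficients equal the minimum-norm solution
        # of the weighted least-squares system with the rank-deficient design.
        fit = fit_ie(study_table_modeled)
        X = build_design(DesignSpec(13, 6)).values
        y = study_table_modeled.deaths.reshape(-1)
        offset = np.log(study_table_modeled.population.reshape(-1))
        mu = fit.fitted_deaths
        z = (np.log(mu) - offset) + (y - mu) / mu
        sw = np.sqrt(mu)
        # rank-deficient system: truncate the near-zero singular value
        theta_pinv = np.linalg.pinv(X * sw[:, None], rcond=1e-8) @ (z * sw)
        assert np.abs(theta_pinv - fit.theta).max() < 1e-6

    def test_minimum_norm_along_null_direction(self, study_table_modeled):
        fit = fit_ie(study_table_modeled)
        norms = [
            np.linalg.norm(fit.theta + c * fit.b0_used) for c in np.linspace(-2, 2, 41)
        ]
        assert np.argmin(norms) == 20  # c = 0

    def test_deviance_flat_along_null_direction(self, study_table_modeled):
        fit = fit_ie(study_table_modeled)
        X = build_design(DesignSpec(13, 6)).values
        y = study_table_modeled.deaths.reshape(-1)
        offset = np.log(study_table_modeled.population.reshape(-1))
        base = fit.deviance
        for c in (-1.0, 0.5, 2.0):
            shifted = np.exp(offset + X @ (fit.theta + c * fit.b0_used))
            assert deviance(y, shifted) == pytest.approx(base, abs=1e-6)

    def test_agrees_with_statsmodels_glm_on_reduced_design(self, study_table_modeled):
        statsmodels = pytest.importorskip("statsmodels.api")
        fit = fit_ie(study_table_modeled)
        X = build_design(DesignSpec(13, 6)).values
        V = scipy.linalg.null_space(fit.b0_used[None, :])
        glm = statsmodels.GLM(
            study_table_modeled.deaths.reshape(-1),
            X @ V,
            family=statsmodels.families.Poisson(),
            offset=np.log(study_table_modeled.population.reshape(-1)),
        ).fit()
        np.testing.assert_allclose(V @ glm.params, fit.theta, atol=1e-6)

    def test_log_likelihood_consistent_with_deviance(self, study_table_modeled):
        # deviance = 2 * (saturated loglik - model loglik)
        fit = fit_ie(study_table_modeled)
        y = study_table_modeled.deaths.reshape(-1)
        saturated = poisson_log_likelihood(y, np.maximum(y, 1e-300))
        assert fit.deviance == pytest.approx(2 * (saturated - fit.log_lik), rel=1e-9)
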