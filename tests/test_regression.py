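import math

import numpy as np
import pytest

from crowdsim.regression import (
    RankDeficientDesignError,
    fit_polynomial,
    linear_scaling_r2,
    loocv_rmse,
    loocv_select,
    monomial_exponents,
)


class TestMonomialBasis:
    @pytest.mark.parametrize("dim,degree", [(1, 4), (2, 5), (3, 2)])
    def test_coefficient_count_is_binomial(self, dim, degree):
        assert len(monomial_exponents(dim, degree)) == math.comb(degree + dim, dim)

    def test_constant_term_first(self):
        assert monomial_exponents(2, 3)[0] == (0, 0)


class TestFitPolynomial:
    def test_exact_quadratic_recovered(self, rng):
        x = np.linspace(0.1, 0.45, 40)
        y = 3.0 - 2.0 * x + 5.0 * x**2
        m = fit_polynomial(x, y, 2)
        np.testing.assert_allclose(m.coefficients, [3.0, -2.0, 5.0], atol=1e-10)
        np.testing.assert_allclose(m.predict(x), y, atol=1e-10)
        assert m.training_rmse < 1e-10

    def test_degree_zero_fits_the_mean(self, rng):
        y = rng.normal(size=25)
        m = fit_polynomial(np.linspace(0, 1, 25), y, 0)
        assert m.coefficients[0] == pytest.approx(y.mean(), rel=1e-12)

    def test_noisy_coefficients_within_three_standard_errors(self, rng):
        n = 400
        x = rng.uniform(0.1, 0.45, n)
        sigma = 0.05
        true = np.array([1.0, -4.0, 7.0])
        y = true[0] + true[1] * x + true[2] * x**2 + rng.normal(0, sigma, n)
        m = fit_polynomial(x, y, 2)
        design = np.column_stack([np.ones(n), x, x**2])
        cov = sigma**2 * np.linalg.inv(design.T @ design)
        se = np.sqrt(np.diag(cov))
        assert np.all(np.abs(m.coefficients - true) < 3.5 * se)

    def test_two_predictor_surface_recovered(self):
        a = np.repeat(np.linspace(1.6, 2.4, 5), 8)
        c = np.tile(np.linspace(0.1, 0.45, 8), 5)
        y = 0.5 + 1.2 * a - 3.0 * c + 0.7 * a * c
        m = fit_polynomial(np.column_stack([a, c]), y, 2)
        np.testing.assert_allclose(m.predict(np.column_stack([a, c])), y, atol=1e-9)

    def test_collinear_design_raises(self):
        x = np.full(30, 0.3)  # no variation: degree-1 design is rank 1
        with pytest.raises(RankDeficientDesignError):
            fit_polynomial(x, np.ones(30), 1)


class TestLoocv:
    def test_hat_identity_matches_explicit_refit(self, rng):
        x = rng.uniform(0, 1, 30)
        y = 1 + x + rng.normal(0, 0.1, 30)
        fast = loocv_rmse(x, y, 2)
        errs = []
        for i in range(30):
            keep = np.arange(30) != i
            m = fit_polynomial(x[keep], y[keep], 2)
            errs.append(y[i] - m.predict([[x[i]]])[0])
        assert fast == pytest.approx(float(np.sqrt(np.mean(np.square(errs)))), rel=1e-9)

    def test_noiseless_cubic_selects_degree_three(self):
        x = np.linspace(0.1, 0.45, 40)
        y = 1 - x + 2 * x**2 - 4 * x**3
        best, rmse = loocv_select(x, y, range(7))
        assert best == 3
        # every degree >= 3 interpolates to numerical noise
        assert rmse[3] < 1e-3 * rmse[2]

    def test_noisy_data_prefers_true_degree_over_overfit(self, rng):
        x = np.repeat(np.linspace(0.1, 0.45, 8), 10)
        y = 2 + 3 * x - 5 * x**2 + rng.normal(0, 0.05, len(x))
        best, rmse = loocv_select(x, y, range(7))
        assert best in (2, 3)  # the quadratic or a marginal neighbour
        assert rmse[best] < rmse[6]

    def test_unidentifiable_degrees_are_infinite(self):
        assert math.isinf(loocv_rmse(np.linspace(0, 1, 4), np.ones(4), 5))


def test_linear_scaling_reduction_on_proportional_curves(rng):
    grid = np.linspace(0.1, 0.45, 8)
    base = 1.0 + 8.0 * grid**2
    curves = {b: b * base * (1 + rng.normal(0, 0.01, 8)) for b in (0.1, 0.3, 0.5, 0.7, 0.9)}
    assert linear_scaling_r2(curves, 0.7) > 0.95


def test_linear_scaling_rejects_non_proportional_family(rng):
    grid = np.linspace(0.1, 0.45, 8)
    curves = {
        1.6: 1.0 + 40.0 * grid**4,
        2.0: np.full(8, 2.0),
        2.4: 3.0 - 5.0 * grid,
    }
    assert linear_scaling_r2(curves, 2.0) < 0.95
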