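"""AR(p) likelihoods, fitting, order selection, and MA representation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import eilcast.ar as ar_mod
from eilcast import (
    ARModel,
    DomainError,
    InsufficientDataError,
    NonStationaryError,
    SimulationConfig,
    YearlySeries,
    aic,
    ar_to_pacf,
    check_stationarity,
    fit_ar,
    log_likelihood_conditional,
    log_likelihood_exact,
    ma_representation,
    pacf_to_ar,
    select_order,
    simulate_ar,
    stationary_autocovariances,
)
from tests.conftest import make_series, mvn_exact_loglik_oracle, random_stationary_coeffs


class TestStationarity:
    def test_ar1_root_modulus(self):
        ok, moduli = check_stationarity([0.5])
        assert ok and moduli[0] == pytest.approx(2.0)

    def test_unit_root_rejected(self):
        ok, moduli = check_stationarity([1.0])
        assert not ok and moduli[0] == pytest.approx(1.0)

    def test_zero_coefficients_are_stationary(self):
        ok, _ = check_stationarity([0.0, 0.0])
        assert ok

    @settings(derandomize=True, max_examples=100)
    @given(
        st.lists(st.floats(-0.95, 0.95), min_size=1, max_size=4),
    )
    def test_pacf_parameterization_always_stationary(self, partials):
        coeffs = pacf_to_ar(np.asarray(partials))
        ok, moduli = check_stationarity(coeffs)
        assert ok, f"partials {partials} -> coeffs {coeffs}, moduli {moduli}"

    def test_pacf_roundtrip(self, rng):
        for p in (1, 2, 3, 4):
            partials = rng.uniform(-0.9, 0.9, size=p)
            back = ar_to_pacf(pacf_to_ar(partials))
            assert np.allclose(back, partials, atol=1e-12)


class TestConditionalLikelihood:
    def test_standard_normal_zeros(self):
        """White-noise model on [0,0,0]: two N(0,1) densities at zero."""
        model = ARModel(p=1, coeffs=[0.0], intercept=0.0, sigma2=1.0)
        ll = log_likelihood_conditional(model, make_series([0.0, 0.0, 0.0]))
        assert ll == pytest.approx(-math.log(2 * math.pi), abs=1e-12)

    def test_sum_of_gaussian_densities(self, rng):
        """Equals the brute-force sum of per-term normal log densities."""
        from scipy.stats import norm

        for p in (1, 2, 3):
            coeffs = random_stationary_coeffs(rng, p)
            model = ARModel(p=p, coeffs=coeffs, intercept=0.4, sigma2=1.7)
            y = rng.normal(2.0, 1.0, size=15)
            series = make_series(y)
            expected = 0.0
            for t in range(p, len(y)):
                pred = model.intercept + sum(
                    coeffs[j] * y[t - 1 - j] for j in range(p)
                )
                expected += norm.logpdf(y[t], loc=pred, scale=math.sqrt(1.7))
            assert log_likelihood_conditional(model, series) == pytest.approx(expected, abs=1e-10)

    def test_scale_invariance_of_standardized_residuals(self, rng):
        """y -> cy, u -> cu, sigma -> c*sigma shifts loglik by -(n-p)*log c."""
        y = rng.normal(5.0, 1.0, size=12)
        c = 3.7
        m1 = ARModel(p=1, coeffs=[0.4], intercept=1.0, sigma2=1.0)
        m2 = ARModel(p=1, coeffs=[0.4], intercept=c, sigma2=c**2)
        ll1 = log_likelihood_conditional(m1, make_series(y))
        ll2 = log_likelihood_conditional(m2, make_series(c * y))
        assert ll2 == pytest.approx(ll1 - (len(y) - 1) * math.log(c), abs=1e-9)

    def test_too_short_series(self):
        model = ARModel(p=2, coeffs=[0.3, 0.2], intercept=0.0, sigma2=1.0)
        with pytest.raises(InsufficientDataError):
            log_likelihood_conditional(model, make_series([1.0, 2.0]))


class TestExactLikelihood:
    def test_white_noise_initial_term(self, rng):
        """At a_1 = 0 the initial term is the plain N(mu, sigma^2) density."""
        from scipy.stats import norm

        y = rng.normal(size=8)
        series = make_series(y)
        model = ARModel(p=1, coeffs=[0.0], intercept=0.7, sigma2=2.0)
        expected = log_likelihood_conditional(model, series) + norm.logpdf(
            y[0], loc=0.7, scale=math.sqrt(2.0)
        )
        assert log_likelihood_exact(model, series) == pytest.approx(expected, abs=1e-12)

    def test_ar1_joint_gaussian_oracle(self, rng):
        """Exact loglik equals the n-dim Gaussian with cov a^|i-j| s2/(1-a^2)."""
        a, s2, u = 0.6, 1.3, 0.8
        y = rng.normal(2.0, 1.5, size=12)
        model = ARModel(p=1, coeffs=[a], intercept=u, sigma2=s2)
        series = make_series(y)
        n = len(y)
        cov = np.array([[s2 * a ** abs(i - j) / (1 - a**2) for j in range(n)] for i in range(n)])
        from scipy.stats import multivariate_normal

        mu = u / (1 - a)
        expected = multivariate_normal.logpdf(y, mean=np.full(n, mu), cov=cov)
        assert log_likelihood_exact(model, series) == pytest.approx(expected, abs=1e-8)

    def test_matches_mvn_oracle_random_models(self, rng):
        for _ in range(25):
            p = int(rng.integers(1, 4))
            coeffs = random_stationary_coeffs(rng, p)
            sigma2 = float(rng.uniform(0.2, 3.0))
            intercept = float(rng.uniform(-1.0, 1.0))
            n = int(rng.integers(p + 2, 21))
            y = rng.normal(0.0, 2.0, size=n)
            model = ARModel(p=p, coeffs=coeffs, intercept=intercept, sigma2=sigma2)
            got = log_likelihood_exact(model, make_series(y))
            want = mvn_exact_loglik_oracle(coeffs, intercept, sigma2, y)
            assert got == pytest.approx(want, abs=1e-8)

    def test_statsmodels_kalman_cross_check(self, rng):
        """Exact likelihood agrees with the state-space (Kalman) evaluation."""
        import statsmodels.api as sm

        y = rng.normal(3.0, 1.0, size=30)
        for p, coeffs in ((1, [0.5]), (2, [0.4, -0.3])):
            model = ARModel(p=p, coeffs=coeffs, intercept=1.2, sigma2=0.9)
            sar = sm.tsa.SARIMAX(y, order=(p, 0, 0), trend="c")
            want = sar.loglike(np.r_[1.2, coeffs, 0.9])
            got = log_likelihood_exact(model, make_series(y))
            assert got == pytest.approx(want, abs=1e-8)

    def test_yule_walker_autocovariances(self):
        g = stationary_autocovariances([0.6], 1.3, 4)
        assert g[0] == pytest.approx(1.3 / (1 - 0.36))
        assert np.allclose(g[1:] / g[:-1], 0.6)
        with pytest.raises(NonStationaryError):
            stationary_autocovariances([1.01], 1.0, 2)


class TestFitAr:
    def test_conditional_ar1_equals_ols(self, rng):
        """The conditional MLE is OLS of y_t on (1, y_{t-1}), closed form."""
        y = rng.normal(2.0, 1.0, size=40)
        model = fit_ar(make_series(y), 1, method="conditional")
        X = np.column_stack([np.ones(39), y[:-1]])
        beta = np.linalg.solve(X.T @ X, X.T @ y[1:])
        assert model.intercept == pytest.approx(beta[0], abs=1e-10)
        assert model.coeffs[0] == pytest.approx(beta[1], abs=1e-10)
        resid = y[1:] - X @ beta
        assert model.sigma2 == pytest.approx(resid @ resid / 39, abs=1e-10)

    def test_ar1_parameter_recovery(self):
        cfg = SimulationConfig(coeffs=[0.6], intercept=1.0, sigma2=1.0, n=1000, seed=42)
        series = simulate_ar(cfg)
        for method in ("conditional", "exact"):
            model = fit_ar(series, 1, method=method)
            assert model.coeffs[0] == pytest.approx(0.6, abs=0.08)
            assert model.mean == pytest.approx(2.5, abs=0.3)
            assert model.sigma2 == pytest.approx(1.0, abs=0.15)

    def test_white_noise_coefficient_near_zero(self):
        cfg = SimulationConfig(coeffs=[0.0], intercept=0.0, sigma2=1.0, n=2000, seed=7)
        model = fit_ar(simulate_ar(cfg), 1, method="exact")
        assert abs(model.coeffs[0]) < 2 / math.sqrt(2000)

    def test_exact_fit_beats_any_nearby_model(self):
        """The optimizer's exact loglik is a local maximum of the likelihood."""
        cfg = SimulationConfig(coeffs=[0.5], intercept=1.0, sigma2=1.0, n=80, seed=3)
        series = simulate_ar(cfg)
        model = fit_ar(series, 1, method="exact")
        for da in (-0.02, 0.02):
            other = ARModel(
                p=1, coeffs=[model.coeffs[0] + da], intercept=model.intercept,
                sigma2=model.sigma2,
            )
            assert log_likelihood_exact(other, series) <= model.loglik + 1e-9

    def test_exact_and_conditional_converge(self):
        cfg = SimulationConfig(coeffs=[0.5], intercept=1.0, sigma2=1.0, n=5000, seed=11)
        series = simulate_ar(cfg)
        a_cond = fit_ar(series, 1, method="conditional").coeffs[0]
        a_exact = fit_ar(series, 1, method="exact").coeffs[0]
        assert abs(a_exact - a_cond) < 0.01

    def test_zero_mean_fit(self):
        cfg = SimulationConfig(coeffs=[0.5], intercept=0.0, sigma2=1.0, n=500, seed=5)
        model = fit_ar(simulate_ar(cfg), 1, method="exact", zero_mean=True)
        assert model.intercept == 0.0
        assert model.n_params == 2
        assert model.coeffs[0] == pytest.approx(0.5, abs=0.12)

    def test_constant_series_rejected(self):
        with pytest.raises(DomainError):
            fit_ar(make_series([3.0] * 10), 1)

    def test_too_short_series_rejected(self):
        with pytest.raises(InsufficientDataError):
            fit_ar(make_series([1.0, 2.0, 1.5]), 1)


class TestAic:
    @pytest.mark.parametrize(
        "loglik, rho, expected", [(-10.0, 2, 24.0), (0.0, 0, 0.0), (5.5, 3, -5.0)]
    )
    def test_direct_values(self, loglik, rho, expected):
        assert aic(loglik, rho) == expected

    def test_each_parameter_costs_two(self):
        assert aic(-7.0, 4) - aic(-7.0, 3) == 2.0

    def test_fitted_model_aic_consistent(self):
        cfg = SimulationConfig(coeffs=[0.4], intercept=1.0, sigma2=1.0, n=60, seed=9)
        model = fit_ar(simulate_ar(cfg), 2, method="exact")
        assert model.aic == -2.0 * model.loglik + 2.0 * model.n_params
        assert model.n_params == 4  # a_1, a_2, intercept, sigma2


class TestSelectOrder:
    def test_table_shape_and_best(self):
        cfg = SimulationConfig(coeffs=[0.7], intercept=1.0, sigma2=1.0, n=200, seed=13)
        sel = select_order(simulate_ar(cfg), max_p=3)
        assert list(sel.table["order"]) == [1, 2, 3]
        assert sel.best.aic == min(sel.table["aic"])
        assert {"a_1", "a_2", "a_3", "intercept", "sigma2", "loglik", "aic"} <= set(
            sel.table.columns
        )

    def test_tie_breaks_toward_smaller_order(self, monkeypatch):
        """Equal AIC across all orders must return p=1."""

        def fake_fit(series, p, method="exact", zero_mean=False):
            return ARModel(
                p=p, coeffs=[0.1] * p, intercept=0.0, sigma2=1.0,
                loglik=-10.0, loglik_kind=method, n_params=0, aic=20.0,
            )

        monkeypatch.setattr(ar_mod, "fit_ar", fake_fit)
        sel = ar_mod.select_order(make_series(np.arange(30.0) % 7 + 1.0), max_p=3)
        assert sel.best.p == 1

    def test_error_annotated_with_order(self):
        with pytest.raises(InsufficientDataError, match="max_p"):
            select_order(make_series([1.0, 2.0, 3.0]), max_p=3)


class TestMaRepresentation:
    def test_ar1_geometric_weights(self):
        model = ARModel(p=1, coeffs=[0.5], intercept=0.0, sigma2=1.0)
        theta = ma_representation(model, 6)
        assert np.allclose(theta, 0.5 ** np.arange(6))

    def test_white_noise_weights(self):
        model = ARModel(p=1, coeffs=[0.0], intercept=0.0, sigma2=1.0)
        assert np.array_equal(ma_representation(model, 4), [1.0, 0.0, 0.0, 0.0])

    def test_ar2_matches_power_series_division(self):
        """theta_j are the Taylor coefficients of 1/(1 - a1 z - a2 z^2)."""
        a1, a2 = 0.5, -0.3
        model = ARModel(p=2, coeffs=[a1, a2], intercept=0.0, sigma2=1.0)
        n = 12
        theta = ma_representation(model, n)
        # long division: c_j with (1 - a1 z - a2 z^2) * sum c_j z^j = 1
        c = np.zeros(n)
        c[0] = 1.0
        for j in range(1, n):
            c[j] = a1 * c[j - 1] + (a2 * c[j - 2] if j >= 2 else 0.0)
        assert np.allclose(theta, c, atol=1e-14)

    def test_forecast_error_variance_matches_monte_carlo(self, rng):
        """sigma^2 sum theta_j^2 is the h-step forecast-error variance."""
        a, s2, h = 0.7, 1.0, 4
        model = ARModel(p=1, coeffs=[a], intercept=0.0, sigma2=s2)
        theta = ma_representation(model, h)
        predicted_var = s2 * float(np.sum(theta**2))
        errs = []
        for _ in range(4000):
            y = 0.0  # start at the process mean: forecast is a^h * y0 = 0
            path = 0.0
            for _step in range(h):
                path = a * path + rng.normal(0.0, 1.0)
            errs.append(path)
        assert np.var(errs) == pytest.approx(predicted_var, rel=0.1)


def test_parameter_recovery_study():
    """Mean and spread of the AR(1) estimator across 200 seeded replicates."""
    a_true, n = 0.5, 200
    estimates = []
    for seed in range(200):
        cfg = SimulationConfig(coeffs=[a_true], intercept=1.0, sigma2=1.0, n=n, seed=seed)
        estimates.append(fit_ar(simulate_ar(cfg), 1, method="exact").coeffs[0])
    estimates = np.asarray(estimates)
    assert abs(estimates.mean() - a_true) < 0.02
    asymptotic_sd = math.sqrt((1 - a_true**2) / n)
    assert abs(estimates.std() - asymptotic_sd) / asymptotic_sd < 0.5
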