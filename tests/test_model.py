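"""Model components: moderated correlation, covariances, likelihood, priors."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import halfnorm, multivariate_normal, norm

from burstvar import (
    ParameterSet,
    PriorConfig,
    build_model_dataset,
    disturbance_covariance,
    log_likelihood,
    log_prior,
    log_random_effects,
    moderated_correlation,
    stationary_covariance,
)
from burstvar.model import spectral_radius


class TestModeratedCorrelation:
    def test_published_point_estimate(self):
        # link-scale 0.0872 at average exercise identity gives rho ~ 0.087
        assert moderated_correlation(0.0872, 0.0105, 0.0) == pytest.approx(
            0.0870, abs=5e-5)

    def test_zero_intercept(self):
        assert moderated_correlation(0.0, 123.0, 0.0) == 0.0

    def test_saturates_strictly_below_one(self):
        r = moderated_correlation(10.0, 0.0, 0.0)
        assert 0.9999999 < r < 1.0

    @settings(deadline=None, derandomize=True)
    @given(st.floats(-8, 8), st.floats(-2, 2), st.floats(-3, 3))
    def test_image_and_monotonicity(self, a0, a1, x):
        # |linear predictor| <= 14 keeps tanh strictly inside (-1, 1) at
        # double precision; beyond that the math stays in (-1, 1) but the
        # float saturates
        r = moderated_correlation(a0, a1, x)
        assert -1.0 < r < 1.0
        if a1 > 1e-6:
            assert moderated_correlation(a0, a1, x + 0.5) > r
        # odd in the linear predictor
        assert moderated_correlation(-a0, -a1, x) == pytest.approx(-r, abs=1e-12)


class TestDisturbanceCovariance:
    def test_identity_case(self):
        assert np.array_equal(disturbance_covariance(1.0, 1.0, 0.0), np.eye(2))

    def test_published_scale_product(self):
        rho = moderated_correlation(0.0872, 0.0105, 0.0)
        cov = disturbance_covariance(1.2342, 0.5855, rho)
        assert cov[0, 1] == pytest.approx(0.06287, abs=5e-5)
        assert cov[0, 1] == cov[1, 0]

    def test_determinant_closed_form(self):
        cov = disturbance_covariance(1.3, 0.7, 0.4)
        assert np.linalg.det(cov) == pytest.approx(
            1.3 ** 2 * 0.7 ** 2 * (1 - 0.4 ** 2), rel=1e-12)

    def test_degenerate_correlation_rejected(self):
        with pytest.raises(ValueError):
            disturbance_covariance(1.0, 1.0, 1.0)
        with pytest.raises(ValueError):
            disturbance_covariance(-1.0, 1.0, 0.0)


class TestStationaryCovariance:
    def test_zero_dynamics_returns_input(self):
        S = disturbance_covariance(1.2, 0.6, 0.3)
        assert np.allclose(stationary_covariance(np.zeros((2, 2)), S), S)

    def test_diagonal_ar1_closed_form(self):
        B = np.diag([0.5, -0.3])
        S = np.diag([2.0, 0.25])
        out = stationary_covariance(B, S)
        assert np.allclose(out, np.diag([2.0 / (1 - 0.25), 0.25 / (1 - 0.09)]))

    def test_agrees_with_fixed_point_iteration(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            B = rng.uniform(-0.6, 0.6, (2, 2))
            if spectral_radius(B) >= 0.95:
                continue
            S = disturbance_covariance(*rng.uniform(0.3, 2.0, 2), rng.uniform(-0.8, 0.8))
            out = stationary_covariance(B, S)
            it = S.copy()
            for _ in range(10_000):
                it = B @ it @ B.T + S
            assert np.allclose(out, it, atol=1e-10)
            assert np.linalg.norm(out - B @ out @ B.T - S) <= 1e-10

    def test_nonstationary_rejected(self):
        with pytest.raises(ValueError, match="stationary"):
            stationary_covariance(np.array([[0.9, 0.9], [0.9, 0.9]]), np.eye(2))


def _one_person_dataset(rng, T):
    part = pd.DataFrame({
        "person_id": ["x"], "age": [40.0], "gender": ["male"],
        "region": ["high_pollution"], "education": ["university"],
        "ses": ["average"], "exid": [35.0],
    })
    daily = pd.DataFrame({
        "person_id": "x", "date": pd.date_range("2021-06-07", periods=T),
        "ls_mean": rng.uniform(20, 80, T), "pa_rate": rng.uniform(50, 900, T),
    })
    return build_model_dataset(daily, part)


def _random_params(rng, columns):
    while True:
        B = rng.uniform(-0.7, 0.7, (2, 2))
        if spectral_radius(B) < 0.95:
            break
    return ParameterSet(
        delta_L={c: rng.normal(0, 0.5) for c in columns},
        delta_P={c: rng.normal(0, 0.5) for c in columns},
        beta=B, sigma_L=rng.uniform(0.4, 2), sigma_P=rng.uniform(0.4, 2),
        tau_L=1.0, tau_P=1.0,
        alpha0=rng.normal(0, 0.6), alpha1=rng.normal(0, 0.3),
        m=rng.normal(0, 1, (1, 2)),
    )


def _dense_oracle_loglik(ds, params):
    """Joint Gaussian over the whole series, built from mu, B, Sigma directly."""
    mu = ds.X @ np.column_stack([params.delta_vector(ds.columns, "L"),
                                 params.delta_vector(ds.columns, "P")]) + params.m[0]
    rho = moderated_correlation(params.alpha0, params.alpha1, ds.exid_std[0])
    Se = disturbance_covariance(params.sigma_L, params.sigma_P, rho)
    S0 = stationary_covariance(params.beta, Se)
    T = ds.n_rows
    cov = np.zeros((2 * T, 2 * T))
    for t in range(T):
        for s in range(T):
            k = abs(t - s)
            blk = np.linalg.matrix_power(params.beta, k) @ S0
            cov[2 * t:2 * t + 2, 2 * s:2 * s + 2] = blk if t >= s else blk.T
    return multivariate_normal(mean=mu.reshape(-1), cov=cov).logpdf(ds.y.reshape(-1))


class TestLogLikelihood:
    def test_matches_dense_gaussian_oracle(self):
        rng = np.random.default_rng(7)
        datasets = [_one_person_dataset(rng, T) for T in (2, 3, 4)]
        for trial in range(60):
            ds = datasets[trial % 3]
            params = _random_params(rng, ds.columns)
            assert log_likelihood(ds, params) == pytest.approx(
                _dense_oracle_loglik(ds, params), abs=1e-8)

    def test_factorizes_without_dynamics(self):
        rng = np.random.default_rng(8)
        ds = _one_person_dataset(rng, 4)
        params = ParameterSet(
            delta_L={"intercept": 0.4}, delta_P={"intercept": 5.0},
            beta=np.zeros((2, 2)), sigma_L=1.1, sigma_P=0.6,
            tau_L=1.0, tau_P=1.0, alpha0=0.0, alpha1=0.0,
            m=np.zeros((1, 2)))
        ll = log_likelihood(ds, params)
        expected = (norm.logpdf(ds.y[:, 0], loc=0.4, scale=1.1).sum()
                    + norm.logpdf(ds.y[:, 1], loc=5.0, scale=0.6).sum())
        assert ll == pytest.approx(expected, abs=1e-10)

    def test_person_order_invariance(self):
        from burstvar import MarConfig, simulate_dataset
        sim = simulate_dataset(6, seed=4, mar=MarConfig())
        daily = sim.daily
        ds1 = build_model_dataset(daily, sim.participants)
        perm = sim.participants.iloc[::-1].reset_index(drop=True)
        daily2 = daily.sort_values("person_id", ascending=False, kind="stable")
        ds2 = build_model_dataset(daily2, perm)
        rng = np.random.default_rng(0)
        params = _random_params(rng, ds1.columns)
        params = params.with_random_effects(np.tile(rng.normal(0, 1, (1, 2)),
                                                    (6, 1)))
        assert log_likelihood(ds1, params) == pytest.approx(
            log_likelihood(ds2, params), rel=1e-12)

    def test_conditioning_variant_drops_first_days(self):
        rng = np.random.default_rng(9)
        ds = _one_person_dataset(rng, 4)
        params = _random_params(rng, ds.columns)
        full = log_likelihood(ds, params, first_day="stationary")
        cond = log_likelihood(ds, params, first_day="condition")
        assert cond != pytest.approx(full)
        # conditioning removes exactly the first day's stationary marginal
        mu = ds.X @ np.column_stack([params.delta_vector(ds.columns, "L"),
                                     params.delta_vector(ds.columns, "P")])
        rho = moderated_correlation(params.alpha0, params.alpha1, ds.exid_std[0])
        Se = disturbance_covariance(params.sigma_L, params.sigma_P, rho)
        S0 = stationary_covariance(params.beta, Se)
        first_term = multivariate_normal(
            mean=mu[0] + params.m[0], cov=S0).logpdf(ds.y[0])
        assert cond + first_term == pytest.approx(full, abs=1e-9)

    def test_missing_data_rejected_here(self, participants3):
        daily = pd.DataFrame({
            "person_id": ["a", "a"], "date": pd.date_range("2020-01-06", periods=2),
            "ls_mean": [50.0, np.nan], "pa_rate": [100.0, 100.0],
        })
        ds = build_model_dataset(daily, participants3[participants3.person_id == "a"])
        params = _random_params(np.random.default_rng(0), ds.columns)
        with pytest.raises(ValueError, match="missing"):
            log_likelihood(ds, params)


class TestLogPrior:
    def _params(self, **kw):
        base = dict(delta_L={"intercept": 0.0}, delta_P={"intercept": 0.0},
                    beta=np.zeros((2, 2)), sigma_L=1.0, sigma_P=0.5,
                    tau_L=1.0, tau_P=0.4, alpha0=0.1, alpha1=0.0)
        base.update(kw)
        return ParameterSet(**base)

    def test_beta_outside_unit_interval_is_impossible(self):
        bad = self._params()
        bad.beta = np.array([[1.2, 0.0], [0.0, 0.0]])
        assert log_prior(bad) == -np.inf

    def test_negative_sd_is_impossible(self):
        assert log_prior(self._params(sigma_L=-0.5)) == -np.inf

    def test_doubling_halfnormal_scales_shifts_by_closed_form(self):
        params = self._params()
        base, doubled = PriorConfig(), PriorConfig().scaled(2.0)
        diff = log_prior(params, doubled) - log_prior(params, base)
        sds = [params.sigma_L, params.sigma_P, params.tau_L, params.tau_P]
        expected = sum(halfnorm.logpdf(s, scale=2.0) - halfnorm.logpdf(s, scale=1.0)
                       for s in sds)
        assert diff == pytest.approx(expected, abs=1e-12)

    def test_posterior_density_is_additive_and_finite(self):
        rng = np.random.default_rng(10)
        ds = _one_person_dataset(rng, 3)
        params = _random_params(rng, ds.columns)
        total = (log_likelihood(ds, params) + log_prior(params)
                 + log_random_effects(params))
        assert np.isfinite(total)
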