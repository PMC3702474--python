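"""Kalman-filter forecasts versus exact Gaussian conditioning, plus the
prediction-limit conventions."""

import numpy as np
import pytest

from aortaforecast import (
    FittedModel,
    ForecastRequest,
    ModelParameters,
    RequestError,
    baseline_predict,
    conditional_oracle,
    extend_trajectory,
    flag_outside_limits,
    kalman_forecast,
    mean_vector,
)
from aortaforecast.synthetic import DEFAULT_SPEC

from conftest import random_parameters, random_trajectory


def _fit_from(params, spacing=2.4):
    return FittedModel.from_parameters(params, DEFAULT_SPEC, spacing)


def _random_fit(seed):
    p = random_parameters(
        np.random.default_rng(seed), ("intercept",) + DEFAULT_SPEC.covariates
    )
    return _fit_from(p), p


# ---------------------------------------------------------------------------
# baseline prediction
# ---------------------------------------------------------------------------


def test_baseline_degenerate_point_prediction():
    """Intercept ln(20) with zero variance predicts exactly 20 mm with
    zero-width limits."""
    p = ModelParameters(
        covariates=("intercept",) + DEFAULT_SPEC.covariates,
        beta=np.column_stack([np.full(9, np.log(20.0)), np.zeros((9, 9))]),
        sigma_spatial=np.zeros((9, 9)),
        rho=0.0,
        sigma2_meas=np.zeros(9),
    )
    traj = random_trajectory(np.random.default_rng(0), 1)
    res = baseline_predict(_fit_from(p), traj)
    assert np.allclose(res.predicted_mm, 20.0)
    assert np.allclose(res.lower_mm, 20.0)
    assert np.allclose(res.upper_mm, 20.0)


def test_baseline_equals_filter_with_no_priors():
    fit, _ = _random_fit(5)
    traj = random_trajectory(np.random.default_rng(6), 1)
    a = baseline_predict(fit, traj)
    b = kalman_forecast(fit, ForecastRequest(covariates=traj, horizons=(1,)))
    assert np.allclose(a.log_mean, b.log_mean, atol=1e-12)
    assert np.allclose(a.log_sd, b.log_sd, atol=1e-12)


def test_baseline_variance_targets_measurement_by_default():
    fit, p = _random_fit(7)
    traj = random_trajectory(np.random.default_rng(8), 1)
    meas = baseline_predict(fit, traj)
    lat = baseline_predict(fit, traj, target="latent")
    assert np.allclose(
        meas.log_sd**2 - lat.log_sd**2, p.sigma2_meas, atol=1e-12
    )


# ---------------------------------------------------------------------------
# kalman_forecast vs conditional_oracle
# ---------------------------------------------------------------------------


def test_noiseless_full_observation_ar1_closed_form():
    """sigma2 = 0 and all positions observed at the last visit: the one-step
    log-mean is mu_{T+1} + rho (y_T - mu_T) exactly."""
    rng = np.random.default_rng(9)
    p0 = random_parameters(rng, ("intercept",) + DEFAULT_SPEC.covariates)
    p = ModelParameters(
        covariates=p0.covariates, beta=p0.beta,
        sigma_spatial=p0.sigma_spatial, rho=0.7, sigma2_meas=np.zeros(9),
    )
    fit = _fit_from(p)
    traj = random_trajectory(rng, 3)
    mu = mean_vector(p, traj, 3).reshape(3, 9)
    y2 = np.exp(mu[1] + 0.05 * rng.standard_normal(9))
    req = ForecastRequest(
        covariates=traj,
        prior_measurements=np.vstack([np.full(9, np.nan), y2]),
        horizons=(3,),
    )
    res = kalman_forecast(fit, req)
    want = mu[2] + 0.7 * (np.log(y2) - mu[1])
    assert np.allclose(res.log_mean[0], want, atol=1e-10)


@pytest.mark.parametrize("seed", range(50))
def test_kalman_equals_dense_conditioning(seed):
    """50 randomized fits/requests with partial missingness: filter output
    equals the Schur-complement oracle to 1e-8 in mean and SD."""
    rng = np.random.default_rng(seed)
    fit, p = _random_fit(seed + 300)
    T_obs = int(rng.integers(0, 4))
    n_total = int(rng.integers(T_obs + 1, T_obs + 4))
    traj = random_trajectory(rng, n_total)
    mu = mean_vector(p, traj, n_total).reshape(n_total, 9)
    priors = np.full((T_obs, 9), np.nan)
    for t in range(T_obs):
        obs = rng.random(9) < 0.7
        priors[t, obs] = np.exp(mu[t, obs] + 0.1 * rng.standard_normal(obs.sum()))
    horizons = tuple(
        sorted(rng.choice(np.arange(T_obs + 1, n_total + 1),
                          size=int(rng.integers(1, n_total - T_obs + 1)),
                          replace=False).tolist())
    )
    req = ForecastRequest(covariates=traj, prior_measurements=priors,
                          horizons=horizons)
    target = "measurement" if seed % 2 == 0 else "latent"
    a = kalman_forecast(fit, req, target=target)
    b = conditional_oracle(fit, req, target=target)
    assert np.abs(a.log_mean - b.log_mean).max() < 1e-8
    assert np.abs(a.log_sd**2 - b.log_sd**2).max() < 1e-8


def test_oracle_no_observations_gives_marginals():
    fit, p = _random_fit(11)
    traj = random_trajectory(np.random.default_rng(12), 2)
    req = ForecastRequest(covariates=traj, horizons=(1, 2))
    res = conditional_oracle(fit, req)
    mu = mean_vector(p, traj, 2).reshape(2, 9)
    assert np.allclose(res.log_mean, mu, atol=1e-12)
    var = np.diag(p.sigma_spatial) + p.sigma2_meas
    assert np.allclose(res.log_sd**2, var[None, :], atol=1e-12)


def test_oracle_symbolic_two_position_conditioning():
    """Observing two positions at visit 1 and predicting visit 2: matches
    the 2x2 Schur complement written out by hand."""
    fit, p = _random_fit(13)
    rng = np.random.default_rng(14)
    traj = random_trajectory(rng, 2)
    mu = mean_vector(p, traj, 2).reshape(2, 9)
    j, k = 0, 4
    yj, yk = np.exp(mu[0, j] + 0.1), np.exp(mu[0, k] - 0.05)
    priors = np.full((1, 9), np.nan)
    priors[0, j], priors[0, k] = yj, yk
    req = ForecastRequest(covariates=traj, prior_measurements=priors, horizons=(2,))
    res = kalman_forecast(fit, req)

    S, s2, rho = p.sigma_spatial, p.sigma2_meas, p.rho
    a = S[j, j] + s2[j]
    b = S[j, k]
    c = S[k, k] + s2[k]
    det = a * c - b * b
    rj = np.log(yj) - mu[0, j]
    rk = np.log(yk) - mu[0, k]
    for tgt in range(9):
        cross = rho * np.array([S[tgt, j], S[tgt, k]])
        w1 = (c * cross[0] - b * cross[1]) / det
        w2 = (-b * cross[0] + a * cross[1]) / det
        want_mean = mu[1, tgt] + w1 * rj + w2 * rk
        want_var = S[tgt, tgt] + s2[tgt] - (w1 * cross[0] + w2 * cross[1])
        assert abs(res.log_mean[0, tgt] - want_mean) < 1e-10
        assert abs(res.log_sd[0, tgt] ** 2 - want_var) < 1e-10


def test_exact_observation_limit_noiseless():
    """With sigma2 = 0 and a fully observed last visit, the one-step
    predictive variance is exactly (1 - rho^2) Sigma_jj — collapsing to a
    point prediction as rho -> 1 (the exact-observation limit)."""
    rng = np.random.default_rng(15)
    p0 = random_parameters(rng, ("intercept",) + DEFAULT_SPEC.covariates)
    traj = random_trajectory(rng, 3)
    for rho in (0.6, 0.999999):
        p = ModelParameters(
            covariates=p0.covariates, beta=p0.beta,
            sigma_spatial=p0.sigma_spatial, rho=rho, sigma2_meas=np.zeros(9),
        )
        fit = _fit_from(p)
        mu = mean_vector(p, traj, 3).reshape(3, 9)
        y = np.exp(mu[:2] + 0.05 * rng.standard_normal((2, 9)))
        req = ForecastRequest(covariates=traj, prior_measurements=y,
                              horizons=(3,))
        for engine in (kalman_forecast, conditional_oracle):
            var = engine(fit, req).log_sd[0] ** 2
            want = (1 - rho**2) * np.diag(p.sigma_spatial)
            assert np.abs(var - want).max() < 1e-9
    # at rho ~ 1 the prediction is numerically a point
    assert var.max() < 1e-5


# ---------------------------------------------------------------------------
# variance structure
# ---------------------------------------------------------------------------


def test_variance_shrinks_with_more_observed_positions():
    fit, p = _random_fit(16)
    rng = np.random.default_rng(17)
    traj = random_trajectory(rng, 2)
    mu = mean_vector(p, traj, 2).reshape(2, 9)
    prev = None
    for n_obs in (0, 3, 6, 9):
        priors = np.full((1, 9), np.nan)
        priors[0, :n_obs] = np.exp(mu[0, :n_obs])
        req = ForecastRequest(covariates=traj, prior_measurements=priors,
                              horizons=(2,))
        var = kalman_forecast(fit, req).log_sd[0] ** 2
        if prev is not None:
            assert np.all(var <= prev + 1e-12)
        prev = var


def test_variance_monotone_in_horizon_and_converges():
    rng = np.random.default_rng(18)
    p0 = random_parameters(rng, ("intercept",) + DEFAULT_SPEC.covariates)
    p = ModelParameters(
        covariates=p0.covariates, beta=p0.beta,
        sigma_spatial=p0.sigma_spatial, rho=0.8, sigma2_meas=p0.sigma2_meas,
    )
    fit = _fit_from(p)
    traj = random_trajectory(rng, 8)
    mu = mean_vector(p, traj, 8).reshape(8, 9)
    priors = np.exp(mu[:1])
    req = ForecastRequest(covariates=traj, prior_measurements=priors,
                          horizons=tuple(range(2, 9)))
    res = kalman_forecast(fit, req)
    var = res.log_sd**2
    assert np.all(np.diff(var, axis=0) >= -1e-12)
    marginal = np.diag(p.sigma_spatial) + p.sigma2_meas
    assert np.all(var[-1] <= marginal + 1e-12)
    assert np.abs(var[-1] - marginal).max() < 0.8**(2 * 7) * np.diag(p.sigma_spatial).max() + 1e-9


# ---------------------------------------------------------------------------
# flags and request validation
# ---------------------------------------------------------------------------


def test_flags_strict_inequality_convention():
    fit, _ = _random_fit(19)
    traj = random_trajectory(np.random.default_rng(20), 1)
    res = baseline_predict(fit, traj)
    at_mean = res.predicted_mm.copy()
    assert not flag_outside_limits(res, at_mean).any()
    exactly_upper = res.upper_mm.copy()
    assert not flag_outside_limits(res, exactly_upper).any()
    above = res.upper_mm * 1.001
    assert flag_outside_limits(res, above).all()
    with_nan = at_mean.copy()
    with_nan[0, 0] = np.nan
    assert not flag_outside_limits(res, with_nan)[0, 0]


def test_request_validation_errors():
    traj = random_trajectory(np.random.default_rng(21), 3)
    with pytest.raises(RequestError, match="strictly after"):
        ForecastRequest(covariates=traj,
                        prior_measurements=np.full((2, 9), 25.0), horizons=(2,))
    with pytest.raises(RequestError, match="projected covariates"):
        ForecastRequest(covariates=traj, horizons=(5,))
    with pytest.raises(RequestError, match="positive"):
        ForecastRequest(covariates=traj,
                        prior_measurements=np.full((1, 9), -1.0), horizons=(2,))


def test_non_constant_spacing_rejected():
    fit, _ = _random_fit(22)
    traj = random_trajectory(np.random.default_rng(23), 3)
    req = ForecastRequest(
        covariates=traj, prior_measurements=np.full((1, 9), 25.0),
        horizons=(3,), visit_times_years=np.array([0.0, 2.4, 5.9]),
    )
    with pytest.raises(RequestError, match="equally spaced"):
        kalman_forecast(fit, req)


def test_extend_trajectory_advances_age_and_ert():
    traj = random_trajectory(np.random.default_rng(24), 2)
    ext = extend_trajectory(traj, 4, 2.4)
    assert ext.n_visits == 4
    assert np.allclose(np.diff(ext.values["age"]), 2.4)
    assert np.all(np.diff(ext.values["bav"]) == 0)
    if traj.values["ert_duration"][-1] > 0:
        assert ext.values["ert_duration"][-1] > traj.values["ert_duration"][-1]
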