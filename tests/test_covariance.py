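"""Mean/covariance construction and observed-data likelihood, checked
against brute-force oracles."""

import numpy as np
import pytest
from scipy import stats

from aortaforecast import (
    CohortDataset,
    ModelParameters,
    ModelSpec,
    SpecificationError,
    gls_beta,
    marginal_covariance,
    mean_vector,
    observed_loglik,
    reml_loglik,
)
from aortaforecast.covariance import CohortEvaluator, ar1_correlation
from aortaforecast.synthetic import DEFAULT_SPEC

from conftest import random_parameters, random_trajectory


# ---------------------------------------------------------------------------
# mean_vector
# ---------------------------------------------------------------------------


def test_mean_vector_intercept_only():
    params = ModelParameters(
        covariates=("intercept",),
        beta=np.full((9, 1), np.log(20.0)),
        sigma_spatial=np.eye(9),
        rho=0.0,
        sigma2_meas=np.zeros(9),
    )
    rng = np.random.default_rng(0)
    traj = random_trajectory(rng, 3)
    mu = mean_vector(params, traj, 3)
    assert mu.shape == (27,)
    assert np.allclose(mu, np.log(20.0))


def test_mean_vector_matches_scalar_loop(full_spec):
    """Entry (t, j) equals x_t' beta_j, visit-major order."""
    rng = np.random.default_rng(42)
    params = random_parameters(rng, ("intercept",) + full_spec.covariates)
    traj = random_trajectory(rng, 3)
    mu = mean_vector(params, traj, 3)
    X = traj.design_matrix(params.covariates)
    for t in range(3):
        for j in range(9):
            expected = float(X[t] @ params.beta[j])
            assert abs(mu[t * 9 + j] - expected) < 1e-12


def test_mean_vector_linearity_across_visits():
    """A covariate change between visits shifts the mean by coef * change."""
    params = ModelParameters(
        covariates=("intercept", "age"),
        beta=np.column_stack([np.full(9, 3.0), np.full(9, 0.01)]),
        sigma_spatial=np.eye(9),
        rho=0.0,
        sigma2_meas=np.zeros(9),
    )
    from aortaforecast import CovariateTrajectory

    traj = CovariateTrajectory("s", {"age": np.array([40.0, 42.4])})
    mu = mean_vector(params, traj, 2).reshape(2, 9)
    assert np.allclose(mu[1] - mu[0], 0.01 * 2.4)


# ---------------------------------------------------------------------------
# marginal_covariance
# ---------------------------------------------------------------------------


def test_marginal_covariance_single_visit_collapse():
    rng = np.random.default_rng(1)
    p = random_parameters(rng)
    G = marginal_covariance(p, 1)
    assert np.allclose(G, p.sigma_spatial + np.diag(p.sigma2_meas))


def test_marginal_covariance_rho_zero_block_diagonal():
    rng = np.random.default_rng(2)
    p = random_parameters(rng)
    p = ModelParameters(
        covariates=p.covariates, beta=p.beta, sigma_spatial=p.sigma_spatial,
        rho=0.0, sigma2_meas=p.sigma2_meas,
    )
    G = marginal_covariance(p, 3)
    block = p.sigma_spatial + np.diag(p.sigma2_meas)
    for t in range(3):
        for s in range(3):
            sub = G[t * 9:(t + 1) * 9, s * 9:(s + 1) * 9]
            assert np.allclose(sub, block if t == s else 0.0)


@pytest.mark.parametrize("seed", range(5))
def test_marginal_covariance_elementwise_formula(seed):
    """Every entry equals rho^|t-s| Sigma_jk + 1{t=s,j=k} sigma2_j."""
    rng = np.random.default_rng(seed)
    p = random_parameters(rng)
    T = int(rng.integers(1, 5))
    G = marginal_covariance(p, T)
    assert np.allclose(G, G.T, atol=1e-14)
    np.linalg.cholesky(G)  # positive definite for valid params
    for t in range(T):
        for s in range(T):
            for j in range(9):
                for k in range(9):
                    want = p.rho ** abs(t - s) * p.sigma_spatial[j, k]
                    if t == s and j == k:
                        want += p.sigma2_meas[j]
                    assert abs(G[t * 9 + j, s * 9 + k] - want) < 1e-12


# ---------------------------------------------------------------------------
# observed_loglik
# ---------------------------------------------------------------------------


def _dense_oracle_loglik(params, dataset, spec):
    """Independent oracle: scipy dense MVN density on observed sub-vectors."""
    total = 0.0
    G = marginal_covariance(params, dataset.n_visits)
    for i in range(dataset.n_subjects):
        obs = np.flatnonzero(dataset.mask[i].reshape(-1))
        if obs.size == 0:
            continue
        traj = dataset.trajectory(i)
        vals = {k: np.nan_to_num(v) for k, v in traj.values.items()}
        traj.values.update(vals)
        mu = mean_vector(params, traj, dataset.n_visits)
        y = dataset.log_diam[i].reshape(-1)[obs]
        total += stats.multivariate_normal.logpdf(
            y, mean=mu[obs], cov=G[np.ix_(obs, obs)]
        )
    return total


def test_observed_loglik_iid_standard_normal():
    """Sigma=I, sigma2=0, rho=0, beta=0: sum of standard-normal densities."""
    spec = ModelSpec(("age",))
    params = ModelParameters(
        covariates=("intercept", "age"),
        beta=np.zeros((9, 2)),
        sigma_spatial=np.eye(9),
        rho=0.0,
        sigma2_meas=np.zeros(9),
    )
    rng = np.random.default_rng(3)
    logd = rng.normal(0.2, 0.1, size=(1, 1, 9))
    ds = CohortDataset(
        subject_ids=["a"],
        diam_mm=np.exp(logd),
        covariates={"age": np.full((1, 1), 40.0)},
        visit_spacing_years=2.4,
    )
    got = observed_loglik(params, ds, spec)
    want = float(np.sum(stats.norm.logpdf(logd)))
    assert abs(got - want) < 1e-10


def test_observed_loglik_matches_dense_oracle(complete_cohort, truth, full_spec):
    got = observed_loglik(truth, complete_cohort, full_spec)
    want = _dense_oracle_loglik(truth, complete_cohort, full_spec)
    assert abs(got - want) < 1e-8


def test_observed_loglik_marginalizes_missing_visit(complete_cohort, truth, full_spec):
    """Deleting one visit equals the oracle density of the remaining entries."""
    ds = complete_cohort.subset_subjects(range(complete_cohort.n_subjects))
    ds.diam_mm[0, 1, :] = np.nan  # subject 0 misses visit 2
    got = observed_loglik(truth, ds, full_spec)
    want = _dense_oracle_loglik(truth, ds, full_spec)
    assert abs(got - want) < 1e-8


def test_observed_loglik_oracle_equivalence_randomized(full_spec):
    """>=50 randomized small instances with missingness agree with the
    dense MVN oracle to 1e-8."""
    from aortaforecast import GeneratorConfig, apply_dropout, simulate_cohort

    rng = np.random.default_rng(99)
    for k in range(50):
        p = random_parameters(
            np.random.default_rng(1000 + k), ("intercept",) + full_spec.covariates
        )
        cfg = GeneratorConfig(
            n_subjects=int(rng.integers(1, 5)),
            n_visits=int(rng.integers(1, 4)),
            truth=p,
            dropout_rate_per_visit=float(rng.uniform(0, 0.4)),
            seed=int(rng.integers(2**31)),
        )
        ds = apply_dropout(simulate_cohort(cfg), cfg)
        # knock out a few single positions too
        m = ds.mask.copy()
        drop = np.random.default_rng(k).random(m.shape) < 0.1
        ds.diam_mm[drop & m] = np.nan
        if not ds.mask.any():
            continue
        got = observed_loglik(p, ds, full_spec)
        want = _dense_oracle_loglik(p, ds, full_spec)
        assert abs(got - want) < 1e-8, f"instance {k}"


def test_observed_loglik_permutation_invariance(small_cohort, truth, full_spec):
    perm = np.random.default_rng(5).permutation(small_cohort.n_subjects)
    shuffled = small_cohort.subset_subjects(perm)
    a = observed_loglik(truth, small_cohort, full_spec)
    b = observed_loglik(truth, shuffled, full_spec)
    assert abs(a - b) < 1e-9


def test_observed_loglik_scale_invariance_with_intercept_shift(
    small_cohort, truth, full_spec
):
    """Multiplying all diameters by c and adding log c to every intercept
    leaves the log-scale likelihood unchanged."""
    c = 1.7
    scaled = CohortDataset(
        subject_ids=list(small_cohort.subject_ids),
        diam_mm=small_cohort.diam_mm * c,
        covariates={k: v.copy() for k, v in small_cohort.covariates.items()},
        visit_spacing_years=small_cohort.visit_spacing_years,
    )
    beta2 = truth.beta.copy()
    beta2[:, 0] += np.log(c)
    truth2 = ModelParameters(
        covariates=truth.covariates, beta=beta2,
        sigma_spatial=truth.sigma_spatial, rho=truth.rho,
        sigma2_meas=truth.sigma2_meas,
    )
    a = observed_loglik(truth, small_cohort, full_spec)
    b = observed_loglik(truth2, scaled, full_spec)
    assert abs(a - b) < 1e-8


def test_zero_observation_subject_skipped_with_warning(truth, full_spec, small_cohort):
    ds = small_cohort.subset_subjects(range(small_cohort.n_subjects))
    ds.diam_mm[0] = np.nan
    with pytest.warns(UserWarning, match="no observations"):
        observed_loglik(truth, ds, full_spec)


# ---------------------------------------------------------------------------
# reml_loglik / gls_beta
# ---------------------------------------------------------------------------


def test_reml_equals_direct_formula_intercept_only():
    """Intercept-only model on 3 subjects: REML equals the closed-form
    restricted likelihood computed with dense algebra."""
    rng = np.random.default_rng(8)
    p = random_parameters(rng)
    spec = ModelSpec(("age",), shared=frozenset({"age"}))
    # use age with zero effect so the direct formula stays simple
    n, T = 3, 2
    G = marginal_covariance(p, T)
    L = np.linalg.cholesky(G)
    Y = (L @ rng.standard_normal((18, n))).T + 3.0
    ds = CohortDataset(
        subject_ids=[f"s{i}" for i in range(n)],
        diam_mm=np.exp(Y).reshape(n, T, 9),
        covariates={"age": np.tile(rng.normal(40, 5, n)[:, None], (1, T))},
        visit_spacing_years=2.4,
    )
    got = reml_loglik(p, ds, spec)

    # dense oracle: stack all subjects into one big GLS problem
    Gbig = np.kron(np.eye(n), G)
    ybig = Y.reshape(-1)
    Zs = []
    for i in range(n):
        Z = np.zeros((18, 10))
        for t in range(T):
            for j in range(9):
                Z[t * 9 + j, j] = 1.0
                Z[t * 9 + j, 9] = ds.covariates["age"][i, t]
        Zs.append(Z)
    Zbig = np.vstack(Zs)
    Gi = np.linalg.inv(Gbig)
    M = Zbig.T @ Gi @ Zbig
    bhat = np.linalg.solve(M, Zbig.T @ Gi @ ybig)
    r = ybig - Zbig @ bhat
    q = 10
    N = ybig.size
    want = -0.5 * (
        (N - q) * np.log(2 * np.pi)
        + np.linalg.slogdet(Gbig)[1]
        + np.linalg.slogdet(M)[1]
        + r @ Gi @ r
    )
    assert abs(got - want) < 1e-8


def test_reml_invariant_to_covariate_reparameterization(small_cohort, truth):
    """Under an invertible reparameterization X -> XA of the fixed-effect
    design, the restricted likelihood changes by exactly -log|det A|
    (so it is invariant for unit-determinant transforms such as shifts)."""
    spec = ModelSpec(("age", "bsa"))
    p = ModelParameters(
        covariates=("intercept", "age", "bsa"),
        beta=np.zeros((9, 3)),
        sigma_spatial=truth.sigma_spatial,
        rho=truth.rho,
        sigma2_meas=truth.sigma2_meas,
    )
    a = reml_loglik(p, small_cohort, spec)
    # pure shift: absorbed by the intercept, |det A| = 1 -> invariant
    ds_shift = small_cohort.subset_subjects(range(small_cohort.n_subjects))
    ds_shift.covariates["age"] = ds_shift.covariates["age"] + 10.0
    assert abs(reml_loglik(p, ds_shift, spec) - a) < 1e-7
    # scaling one covariate by c rescales its 9 position-specific columns:
    # log|det A| = 9 log c
    ds_scale = small_cohort.subset_subjects(range(small_cohort.n_subjects))
    ds_scale.covariates["age"] = 0.5 * ds_scale.covariates["age"]
    b = reml_loglik(p, ds_scale, spec)
    assert abs((b - a) + 9 * np.log(0.5)) < 1e-7


def test_gls_identity_covariance_reduces_to_ols(full_spec, complete_cohort):
    p = ModelParameters(
        covariates=("intercept",) + full_spec.covariates,
        beta=np.zeros((9, 10)),
        sigma_spatial=np.eye(9),
        rho=0.0,
        sigma2_meas=np.zeros(9),
    )
    res = gls_beta(p, complete_cohort, full_spec)
    # OLS oracle on the stacked design
    from aortaforecast.covariance import build_full_design

    Zs, ys = [], []
    for i in range(complete_cohort.n_subjects):
        X = complete_cohort.trajectory(i).design_matrix(p.covariates)
        Zs.append(build_full_design(X, full_spec))
        ys.append(complete_cohort.log_diam[i].reshape(-1))
    Z = np.vstack(Zs)
    y = np.concatenate(ys)
    want, *_ = np.linalg.lstsq(Z, y, rcond=None)
    assert np.allclose(res.theta, want, atol=1e-8)


def test_gls_recovers_truth_from_noiseless_data(full_spec, truth):
    """With Sigma -> 0 and sigma2 -> 0 the simulated data are exactly the
    model mean and GLS recovers beta to numerical precision."""
    from aortaforecast import GeneratorConfig, simulate_cohort

    noiseless = ModelParameters(
        covariates=truth.covariates, beta=truth.beta,
        sigma_spatial=np.zeros((9, 9)), rho=0.0, sigma2_meas=np.zeros(9),
    )
    ds = simulate_cohort(
        GeneratorConfig(n_subjects=30, seed=5, truth=noiseless,
                        dropout_rate_per_visit=0.0)
    )
    assert np.allclose(
        np.log(ds.diam_mm[0, 0]), truth.beta @
        ds.trajectory(0).design_matrix(truth.covariates)[0], atol=1e-12,
    )
    # any valid working covariance gives the exact answer on noiseless data
    work = ModelParameters(
        covariates=truth.covariates, beta=truth.beta,
        sigma_spatial=np.eye(9) * 0.01, rho=0.5, sigma2_meas=np.full(9, 1e-4),
    )
    res = gls_beta(work, ds, full_spec)
    assert np.abs(res.beta - truth.beta).max() < 1e-8


def test_rank_deficient_design_names_columns(small_cohort):
    ds = small_cohort.subset_subjects(range(small_cohort.n_subjects))
    ds.covariates["bav_copy"] = ds.covariates["bav"].copy()
    spec = ModelSpec(("bav", "bav_copy"))
    with pytest.raises(SpecificationError, match="bav"):
        CohortEvaluator(ds, spec)


def test_gamma_positive_definite_over_random_draws():
    """Cholesky succeeds for every valid random parameter draw."""
    for seed in range(30):
        p = random_parameters(np.random.default_rng(seed))
        T = seed % 4 + 1
        np.linalg.cholesky(marginal_covariance(p, T))


def test_ar1_correlation_values():
    R = ar1_correlation(0.5, 3)
    assert np.allclose(R, [[1, 0.5, 0.25], [0.5, 1, 0.5], [0.25, 0.5, 1]])
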