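import numpy as np
import pytest

from aortaforecast import (
    CovariateTrajectory,
    FitOptions,
    GeneratorConfig,
    ModelParameters,
    ModelSpec,
    default_truth,
    generate_cohort,
    simulate_cohort,
)
from aortaforecast.synthetic import DEFAULT_SPEC


@pytest.fixture(scope="session")
def truth() -> ModelParameters:
    return default_truth()


@pytest.fixture(scope="session")
def full_spec() -> ModelSpec:
    return DEFAULT_SPEC


@pytest.fixture(scope="session")
def small_cohort(truth):
    """12 subjects, 3 visits, with dropout: fast likelihood-level checks."""
    return generate_cohort(GeneratorConfig(n_subjects=12, seed=7))


@pytest.fixture(scope="session")
def complete_cohort(truth):
    """No-dropout cohort for dense-oracle comparisons."""
    return simulate_cohort(GeneratorConfig(n_subjects=12, seed=11, dropout_rate_per_visit=0.0))


@pytest.fixture(scope="session")
def fitted_small(truth, full_spec):
    """One converged REML fit reused by inference/reporting tests."""
    from aortaforecast import fit

    ds = simulate_cohort(
        GeneratorConfig(n_subjects=80, seed=21, dropout_rate_per_visit=0.0)
    )
    return fit(ds, full_spec, FitOptions(restarts=1, seed=0))


def random_parameters(rng: np.random.Generator, covariates=("intercept",)) -> ModelParameters:
    """Random valid parameter set for property checks."""
    A = rng.standard_normal((9, 9)) * 0.1
    Sigma = A @ A.T + 0.05 * np.eye(9)
    return ModelParameters(
        covariates=tuple(covariates),
        beta=rng.standard_normal((9, len(covariates))) * 0.2,
        sigma_spatial=Sigma,
        rho=float(rng.uniform(-0.9, 0.95)),
        sigma2_meas=rng.uniform(0.001, 0.05, size=9),
    )


def random_trajectory(rng: np.random.Generator, n_visits: int, subject_id="S1") -> CovariateTrajectory:
    return CovariateTrajectory(
        subject_id=subject_id,
        values={
            "coarctation": np.full(n_visits, float(rng.random() < 0.12)),
            "age": 30 + 2.4 * np.arange(n_visits) + rng.uniform(0, 10),
            "bav": np.full(n_visits, float(rng.random() < 0.25)),
            "antihypertensive": np.minimum(
                np.cumsum(rng.random(n_visits) < 0.2), 1.0
            ),
            "diastolic_abp": rng.normal(77, 11) + rng.normal(0, 3, n_visits),
            "bsa": np.clip(rng.normal(1.5, 0.2) + rng.normal(0, 0.02, n_visits), 1.0, None),
            "ert_duration": np.maximum(rng.uniform(-5, 15), 0) + 2.4 * np.arange(n_visits),
            "karyotype_45x": np.full(n_visits, float(rng.random() < 0.58)),
            "elongated_arch": np.full(n_visits, float(rng.random() < 0.47)),
        },
    )
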