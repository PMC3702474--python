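"""Synthetic Turner-syndrome cohort generator.

Emulates the study design behind the model: ~100 adult women with Turner
syndrome, nine aortic positions measured by CMR at three visits spaced
~2.4 years apart, visit-level risk factors, and monotone missing-at-random
dropout.  Log-diameters are drawn exactly from the model the analysis
assumes — the generator is the model run forward — so every downstream
stage (likelihood, fitting, inference, forecasting) can be validated
against known truth.

The shipped default truth uses the published position-specific coefficient
estimates for the nine risk factors, with per-position intercepts solved so
that the model's baseline mean diameters (at the covariate means, including
the lognormal variance correction) reproduce the cohort's baseline means.
Covariance components are calibrated from the cohort's baseline dispersion
and the scanner's repeatability; see docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .covariance import marginal_covariance, mean_vector
from .dataset import DEFAULT_COVARIATES, CohortDataset, CovariateTrajectory
from .errors import ConfigurationError
from .params import ModelParameters, ModelSpec
from .positions import N_POSITIONS

DEFAULT_SPEC = ModelSpec(DEFAULT_COVARIATES)

#: Published log-scale coefficients (rows: the 9 positions in canonical
#: order; columns: coarctation, age, bicuspid valve, antihypertensive
#: treatment, diastolic ABP, BSA, ERT duration, 45,X karyotype, elongated
#: transverse arch).
PUBLISHED_BETA = np.array(
    [
        [0.04, 0.0030, 0.100, -0.041, -0.0006, 0.17, 0.0020, -0.06, 0.0357],
        [-0.02, 0.0031, 0.129, -0.007, -0.0005, 0.06, 0.0017, -0.08, 0.0165],
        [-0.06, 0.0060, 0.174, -0.010, 0.0008, 0.05, -0.0003, -0.06, 0.0115],
        [-0.03, 0.0045, 0.078, 0.003, 0.0008, 0.10, -0.0022, -0.03, -0.00001],
        [-0.07, 0.0034, 0.081, -0.012, 0.0001, 0.17, -0.0032, -0.05, -0.0108],
        [-0.06, 0.0009, 0.008, -0.008, 0.0009, 0.16, -0.0009, -0.02, -0.0456],
        [-0.02, 0.0026, 0.024, 0.006, 0.0016, 0.19, -0.0006, -0.03, -0.0241],
        [0.21, 0.0007, 0.051, -0.014, 0.0009, 0.12, 0.0001, -0.04, 0.0037],
        [0.14, 0.0034, 0.047, 0.010, 0.0014, 0.20, -0.0008, -0.04, -0.0163],
    ]
)

#: Baseline cohort diameters, mean and SD in mm per position.
BASELINE_MEAN_MM = np.array([29.1, 25.4, 27.4, 25.4, 23.5, 20.5, 19.3, 19.4, 18.2])
BASELINE_SD_MM = np.array([4.0, 4.7, 6.7, 4.0, 3.7, 2.6, 2.4, 2.9, 2.4])

#: Single-measurement repeatability SD in mm (intra-observer Bland-Altman
#: limits of about +/-1.85 mm on a difference of two readings).
MEAS_ERROR_SD_MM = 0.67

#: Between-position correlation decay per step along the aorta.
SPATIAL_CORR_DECAY = 0.85

#: Latent temporal autocorrelation per ~2.4-year visit interval.
DEFAULT_RHO = 0.9


@dataclass(frozen=True)
class CovariateModel:
    """Baseline distributions and per-visit drift of the risk factors.

    Defaults are calibrated to the adult TS cohort: age ~ N(38, 11) years
    truncated at 18; BSA ~ N(1.5, 0.2) m^2 truncated above 1.0; 24-h
    diastolic ABP ~ N(77, 11) mmHg; bicuspid valve 25%, coarctation 12%,
    45,X karyotype 58%, elongated arch 47%; antihypertensive treatment 29%
    at baseline with possible switch-on at later visits; oestrogen
    replacement in 86%, with duration advancing by the visit spacing.
    """

    age_mean: float = 38.0
    age_sd: float = 11.0
    age_min: float = 18.0
    bav_p: float = 0.25
    coarctation_p: float = 0.12
    karyotype_45x_p: float = 0.58
    elongated_arch_p: float = 0.47
    antihypertensive_baseline_p: float = 0.29
    antihypertensive_switch_p: float = 0.20
    diastolic_abp_mean: float = 77.0
    diastolic_abp_sd: float = 11.0
    diastolic_abp_walk_sd: float = 5.0
    bsa_mean: float = 1.5
    bsa_sd: float = 0.2
    bsa_min: float = 1.0
    bsa_walk_sd: float = 0.03
    ert_p: float = 0.86

    def __post_init__(self):
        for name in (
            "bav_p",
            "coarctation_p",
            "karyotype_45x_p",
            "elongated_arch_p",
            "antihypertensive_baseline_p",
            "antihypertensive_switch_p",
            "ert_p",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        for name in ("age_sd", "diastolic_abp_sd", "bsa_sd"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        for name in ("diastolic_abp_walk_sd", "bsa_walk_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")

    # -- analytic baseline moments (used for intercept calibration) -------
    def baseline_means(self) -> dict[str, float]:
        a = (self.age_min - self.age_mean) / self.age_sd
        age_mean = float(stats.truncnorm.mean(a, np.inf, self.age_mean, self.age_sd))
        b = (self.bsa_min - self.bsa_mean) / self.bsa_sd
        bsa_mean = float(stats.truncnorm.mean(b, np.inf, self.bsa_mean, self.bsa_sd))
        # baseline ERT duration ~ ert_p * Uniform(0, age - age_min)
        ert_mean = self.ert_p * (age_mean - self.age_min) / 2.0
        return {
            "coarctation": self.coarctation_p,
            "age": age_mean,
            "bav": self.bav_p,
            "antihypertensive": self.antihypertensive_baseline_p,
            "diastolic_abp": self.diastolic_abp_mean,
            "bsa": bsa_mean,
            "ert_duration": ert_mean,
            "karyotype_45x": self.karyotype_45x_p,
            "elongated_arch": self.elongated_arch_p,
        }

    def baseline_variances(self) -> dict[str, float]:
        a = (self.age_min - self.age_mean) / self.age_sd
        age_var = float(stats.truncnorm.var(a, np.inf, self.age_mean, self.age_sd))
        age_mean = float(stats.truncnorm.mean(a, np.inf, self.age_mean, self.age_sd))
        b = (self.bsa_min - self.bsa_mean) / self.bsa_sd
        bsa_var = float(stats.truncnorm.var(b, np.inf, self.bsa_mean, self.bsa_sd))
        # duration U ~ Uniform(0, A), A = age - age_min:
        # E[U|A]=A/2, Var(U|A)=A^2/12
        mA = age_mean - self.age_min
        vA = age_var
        eu = mA / 2.0
        eu2 = (vA + mA**2) / 3.0
        p = self.ert_p
        ert_var = p * eu2 - (p * eu) ** 2
        bern = lambda q: q * (1.0 - q)  # noqa: E731
        return {
            "coarctation": bern(self.coarctation_p),
            "age": age_var,
            "bav": bern(self.bav_p),
            "antihypertensive": bern(self.antihypertensive_baseline_p),
            "diastolic_abp": self.diastolic_abp_sd**2,
            "bsa": bsa_var,
            "ert_duration": ert_var,
            "karyotype_45x": bern(self.karyotype_45x_p),
            "elongated_arch": bern(self.elongated_arch_p),
        }


def default_truth(
    covariate_model: CovariateModel | None = None,
    rho: float = DEFAULT_RHO,
) -> ModelParameters:
    """Published-coefficient truth with calibrated covariance and intercepts.

    * Slopes: the published position-specific estimates (``PUBLISHED_BETA``).
    * Residual marginal log-variance per position: total baseline
      log-variance ``log(1 + CV^2)`` minus the part explained by the
      covariates under the default covariate model.
    * Measurement-error variance: scanner repeatability mapped to the log
      scale, ``(0.67 mm / mean_j)^2``.
    * Between-position correlation: ``0.85^|j-k|``.
    * Intercepts: chosen so the model's baseline *arithmetic* mean diameter
      at the covariate means equals the cohort baseline means, i.e.
      ``b0_j = log(mean_j) - v_j/2 - xbar' beta_j`` with ``v_j`` the
      marginal log-variance.
    """
    cm = covariate_model or CovariateModel()
    xbar = cm.baseline_means()
    xvar = cm.baseline_variances()
    names = list(DEFAULT_COVARIATES)

    cv2 = (BASELINE_SD_MM / BASELINE_MEAN_MM) ** 2
    v_total = np.log1p(cv2)
    explained = np.zeros(N_POSITIONS)
    for c_idx, c in enumerate(names):
        explained += PUBLISHED_BETA[:, c_idx] ** 2 * xvar[c]
    v_resid = np.maximum(v_total - explained, 0.006)

    sigma2_meas = (MEAS_ERROR_SD_MM / BASELINE_MEAN_MM) ** 2
    s = np.sqrt(np.maximum(v_resid - sigma2_meas, 1e-4))
    corr = SPATIAL_CORR_DECAY ** np.abs(
        np.subtract.outer(np.arange(N_POSITIONS), np.arange(N_POSITIONS))
    )
    sigma_spatial = corr * np.outer(s, s)

    v_marginal = np.diag(sigma_spatial) + sigma2_meas
    xbar_vec = np.array([xbar[c] for c in names])
    intercept = np.log(BASELINE_MEAN_MM) - v_marginal / 2.0 - PUBLISHED_BETA @ xbar_vec
    beta = np.column_stack([intercept, PUBLISHED_BETA])
    return ModelParameters(
        covariates=("intercept",) + tuple(names),
        beta=beta,
        sigma_spatial=sigma_spatial,
        rho=rho,
        sigma2_meas=sigma2_meas,
    )


@dataclass(frozen=True)
class GeneratorConfig:
    """Cohort-simulation settings; defaults reproduce the study design."""

    n_subjects: int = 102
    n_visits: int = 3
    visit_spacing_years: float = 2.4
    truth: ModelParameters = field(default_factory=default_truth)
    covariate_model: CovariateModel = field(default_factory=CovariateModel)
    dropout_rate_per_visit: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 1:
            raise ConfigurationError("n_subjects must be >= 1")
        if self.n_visits < 1:
            raise ConfigurationError("n_visits must be >= 1")
        if self.visit_spacing_years <= 0:
            raise ConfigurationError("visit_spacing_years must be positive")
        if not 0.0 <= self.dropout_rate_per_visit <= 1.0:
            raise ConfigurationError("dropout_rate_per_visit must be in [0, 1]")


def _streams(seed: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(3)]


def sample_covariates(config: GeneratorConfig) -> list[CovariateTrajectory]:
    """Draw per-subject covariate trajectories over all visits.

    Age and ERT duration advance deterministically by the visit spacing;
    diastolic ABP and BSA follow small random walks; antihypertensive
    treatment can only switch on.  Congenital indicators are time-constant.
    """
    rng = _streams(config.seed)[0]
    cm = config.covariate_model
    n, T = config.n_subjects, config.n_visits
    dt = config.visit_spacing_years

    a = (cm.age_min - cm.age_mean) / cm.age_sd
    age0 = stats.truncnorm.rvs(
        a, np.inf, cm.age_mean, cm.age_sd, size=n, random_state=rng
    )
    b = (cm.bsa_min - cm.bsa_mean) / cm.bsa_sd
    bsa0 = stats.truncnorm.rvs(
        b, np.inf, cm.bsa_mean, cm.bsa_sd, size=n, random_state=rng
    )
    dabp0 = rng.normal(cm.diastolic_abp_mean, cm.diastolic_abp_sd, size=n)
    bav = (rng.random(n) < cm.bav_p).astype(float)
    coa = (rng.random(n) < cm.coarctation_p).astype(float)
    kar = (rng.random(n) < cm.karyotype_45x_p).astype(float)
    eta = (rng.random(n) < cm.elongated_arch_p).astype(float)
    on_ert = rng.random(n) < cm.ert_p
    ert0 = np.where(on_ert, rng.uniform(0.0, np.maximum(age0 - cm.age_min, 0.0)), 0.0)
    aht0 = rng.random(n) < cm.antihypertensive_baseline_p

    steps = np.arange(T) * dt
    age = age0[:, None] + steps[None, :]
    ert = np.where(on_ert[:, None], ert0[:, None] + steps[None, :], 0.0)

    dabp = np.empty((n, T))
    bsa = np.empty((n, T))
    dabp[:, 0] = dabp0
    bsa[:, 0] = bsa0
    for t in range(1, T):
        dabp[:, t] = dabp[:, t - 1] + rng.normal(0, cm.diastolic_abp_walk_sd, size=n)
        bsa[:, t] = np.maximum(
            bsa[:, t - 1] + rng.normal(0, cm.bsa_walk_sd, size=n), 0.5
        )

    aht = np.empty((n, T))
    on = aht0.copy()
    aht[:, 0] = on
    for t in range(1, T):
        on = on | (rng.random(n) < cm.antihypertensive_switch_p)
        aht[:, t] = on

    out = []
    for i in range(n):
        out.append(
            CovariateTrajectory(
                subject_id=f"TS{i + 1:04d}",
                values={
                    "coarctation": np.full(T, coa[i]),
                    "age": age[i],
                    "bav": np.full(T, bav[i]),
                    "antihypertensive": aht[i],
                    "diastolic_abp": dabp[i],
                    "bsa": bsa[i],
                    "ert_duration": ert[i],
                    "karyotype_45x": np.full(T, kar[i]),
                    "elongated_arch": np.full(T, eta[i]),
                },
            )
        )
    return out


def _covariance_sqrt(G: np.ndarray) -> np.ndarray:
    """Lower-triangular-ish square root; handles the PSD boundary."""
    try:
        return np.linalg.cholesky(G)
    except np.linalg.LinAlgError:
        w, V = np.linalg.eigh(G)
        return V * np.sqrt(np.maximum(w, 0.0))


def simulate_cohort(config: GeneratorConfig) -> CohortDataset:
    """Simulate a complete (no-dropout) cohort from the configured truth.

    Each subject's stacked 9 x n_visits log-diameter vector is drawn from a
    multivariate normal with the model's mean and marginal covariance.
    Bit-reproducible for a fixed config and seed.
    """
    trajs = sample_covariates(config)
    noise_rng = _streams(config.seed)[1]
    n, T = config.n_subjects, config.n_visits
    dim = T * N_POSITIONS

    means = np.stack([mean_vector(config.truth, tr, T) for tr in trajs])
    Gam = marginal_covariance(config.truth, T)
    root = _covariance_sqrt(Gam)
    logy = means + noise_rng.standard_normal((n, dim)) @ root.T
    diam = np.exp(logy).reshape(n, T, N_POSITIONS)

    covariates = {
        name: np.stack([tr.values[name] for tr in trajs])
        for name in trajs[0].values
    }
    return CohortDataset(
        subject_ids=[tr.subject_id for tr in trajs],
        diam_mm=diam,
        covariates=covariates,
        visit_spacing_years=config.visit_spacing_years,
    )


def apply_dropout(dataset: CohortDataset, config: GeneratorConfig) -> CohortDataset:
    """Apply monotone missing-at-random dropout after the baseline visit.

    Each subject independently leaves the study before each post-baseline
    visit with probability ``dropout_rate_per_visit``; once lost, all later
    visits are missing.  Retained measurements are untouched; dropout does
    not depend on the diameters (MAR).
    """
    rate = config.dropout_rate_per_visit
    if rate == 0.0 or dataset.n_visits == 1:
        return dataset
    rng = _streams(config.seed)[2]
    n, T = dataset.n_subjects, dataset.n_visits
    retained = np.ones((n, T), dtype=bool)
    alive = np.ones(n, dtype=bool)
    for t in range(1, T):
        alive &= rng.random(n) >= rate
        retained[:, t] = alive
    diam = dataset.diam_mm.copy()
    diam[~retained] = np.nan
    covs = {k: np.where(retained, v, np.nan) for k, v in dataset.covariates.items()}
    return CohortDataset(
        subject_ids=list(dataset.subject_ids),
        diam_mm=diam,
        covariates=covs,
        visit_spacing_years=dataset.visit_spacing_years,
    )


def generate_cohort(config: GeneratorConfig) -> CohortDataset:
    """Simulate and apply dropout in one call."""
    return apply_dropout(simulate_cohort(config), config)


def truth_without_effect(truth: ModelParameters, covariate: str) -> ModelParameters:
    """Copy of a truth parameter set with one covariate's effect zeroed
    (handy for null simulations)."""
    c = truth.covariates.index(covariate)
    beta = truth.beta.copy()
    beta[:, c] = 0.0
    return replace(truth, beta=beta)
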