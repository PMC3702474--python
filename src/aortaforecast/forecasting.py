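"""Per-position diameter forecasts with 95% prediction limits.

The fitted model admits an exact state-space form over equally spaced
visits.  The state ``alpha_t`` is the 9-vector of true (error-free) log
diameters:

    alpha_1 ~ N(mu_1, Sigma)
    alpha_t = mu_t + rho (alpha_{t-1} - mu_{t-1}) + eta_t,
                                        eta_t ~ N(0, (1 - rho^2) Sigma)
    y_t     = alpha_t + eps_t,          eps_t ~ N(0, diag(sigma2_meas))

where ``mu_t = X_t beta`` comes from the subject's (observed or projected)
risk factors.  Filtering this system over the prior measurements and
propagating to a future visit is algebraically identical to conditioning
the joint Gaussian ``Cov(y) = R(rho) (x) Sigma + I (x) D`` on the observed
entries; the brute-force conditioning is kept as an independent oracle.

Prediction limits target the future *measurement* (they include the
measurement-error variance) because that is what a new CMR reading is
compared against; latent-scale limits are available via ``target``.
Limits are computed on the log scale as mean +/- 1.96 SD and exponentiated,
hence asymmetric in mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .covariance import marginal_covariance, mean_vector
from .dataset import CovariateTrajectory
from .errors import RequestError
from .fitting import FittedModel
from .positions import N_POSITIONS, POSITIONS

Z_95 = 1.959963984540054  # two-sided 95% normal quantile

_ORACLE_MAX_VISITS = 8


@dataclass
class ForecastRequest:
    """A subject's covariates, prior measurements and requested horizons.

    ``prior_measurements`` is (T_obs, 9) in mm with NaN for unmeasured
    positions (T_obs may be 0).  ``horizons`` are 1-based visit indices on
    the fitted equally spaced visit grid, strictly after the last observed
    visit.  ``covariates`` must cover every visit up to the last horizon.
    ``visit_times_years``, if given, must be equally spaced at the fitted
    interval (the autoregression is defined per constant visit interval).
    """

    covariates: CovariateTrajectory
    prior_measurements: np.ndarray = field(
        default_factory=lambda: np.empty((0, N_POSITIONS))
    )
    horizons: tuple[int, ...] = (1,)
    visit_times_years: np.ndarray | None = None

    def __post_init__(self):
        self.prior_measurements = np.asarray(
            self.prior_measurements, dtype=float
        ).reshape(-1, N_POSITIONS)
        self.horizons = tuple(int(h) for h in self.horizons)
        if not self.horizons:
            raise RequestError("at least one forecast horizon is required")
        t_obs = self.prior_measurements.shape[0]
        if min(self.horizons) <= t_obs:
            raise RequestError(
                f"horizons must lie strictly after the last observed visit "
                f"({t_obs}); got {self.horizons}"
            )
        if self.covariates.n_visits < max(self.horizons):
            raise RequestError(
                "projected covariates must be present for every horizon: "
                f"trajectory covers {self.covariates.n_visits} visits, "
                f"last horizon is {max(self.horizons)}"
            )
        with np.errstate(invalid="ignore"):
            if np.any(self.prior_measurements <= 0):
                raise RequestError("prior measurements must be positive (mm)")

    @property
    def n_observed(self) -> int:
        return self.prior_measurements.shape[0]

    def check_spacing(self, fitted_spacing: float) -> None:
        if self.visit_times_years is None:
            return
        t = np.asarray(self.visit_times_years, dtype=float)
        if t.size >= 2:
            d = np.diff(t)
            if np.ptp(d) > 1e-6 * max(1.0, abs(d[0])):
                raise RequestError(
                    "visits are not equally spaced; the autoregressive term "
                    "is defined only for a constant inter-visit interval"
                )
            if abs(d[0] - fitted_spacing) > 0.05 * fitted_spacing:
                raise RequestError(
                    f"visit spacing {d[0]:.3g} y differs from the fitted "
                    f"interval {fitted_spacing:.3g} y; forecasts step in "
                    "units of the fitted spacing"
                )


@dataclass
class ForecastResult:
    """Per horizon x position predictions with 95% limits (mm).

    ``prior_*`` fields hold, per prior visit, the one-step-ahead predictive
    distribution that each measurement was compared against, and the
    outside-limits flag.
    """

    horizons: tuple[int, ...]
    log_mean: np.ndarray           # (H, 9)
    log_sd: np.ndarray             # (H, 9)
    target: str = "measurement"
    prior_log_mean: np.ndarray | None = None   # (T_obs, 9)
    prior_log_sd: np.ndarray | None = None
    prior_flags: np.ndarray | None = None      # (T_obs, 9) bool

    @property
    def predicted_mm(self) -> np.ndarray:
        return np.exp(self.log_mean)

    @property
    def lower_mm(self) -> np.ndarray:
        return np.exp(self.log_mean - Z_95 * self.log_sd)

    @property
    def upper_mm(self) -> np.ndarray:
        return np.exp(self.log_mean + Z_95 * self.log_sd)

    def to_frame(self, measured: np.ndarray | None = None) -> pd.DataFrame:
        """Plot-ready long table: position, horizon, mean and limits."""
        rows = []
        flags = (
            flag_outside_limits(self, measured) if measured is not None else None
        )
        for h_idx, h in enumerate(self.horizons):
            for j, pos in enumerate(POSITIONS):
                row = {
                    "horizon": h,
                    "position": pos,
                    "predicted_mm": self.predicted_mm[h_idx, j],
                    "lower_mm": self.lower_mm[h_idx, j],
                    "upper_mm": self.upper_mm[h_idx, j],
                    "log_mean": self.log_mean[h_idx, j],
                    "log_sd": self.log_sd[h_idx, j],
                }
                if measured is not None:
                    m = np.asarray(measured, dtype=float).reshape(-1, N_POSITIONS)
                    row["measured_mm"] = m[h_idx, j]
                    row["outside_limits"] = bool(flags[h_idx, j])
                rows.append(row)
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        d = {
            "horizons": list(self.horizons),
            "positions": list(POSITIONS),
            "target": self.target,
            "predicted_mm": self.predicted_mm.tolist(),
            "lower_mm": self.lower_mm.tolist(),
            "upper_mm": self.upper_mm.tolist(),
            "log_mean": self.log_mean.tolist(),
            "log_sd": self.log_sd.tolist(),
        }
        if self.prior_flags is not None:
            d["prior_outside_limits"] = self.prior_flags.tolist()
        return d


def _means_by_visit(fit: FittedModel, traj: CovariateTrajectory, n_visits: int):
    return mean_vector(fit.params, traj, n_visits).reshape(n_visits, N_POSITIONS)


def baseline_predict(
    fit: FittedModel, covariates: CovariateTrajectory, target: str = "measurement"
) -> ForecastResult:
    """Prediction from risk factors alone, without prior measurements.

    Per position: log-mean ``x' beta_j`` and log-variance ``Sigma_jj +
    sigma2_j`` (the marginal distribution of a single visit).
    """
    mu = _means_by_visit(fit, covariates, 1)
    var = np.diag(fit.params.sigma_spatial).copy()
    if target == "measurement":
        var = var + fit.params.sigma2_meas
    elif target != "latent":
        raise RequestError("target must be 'measurement' or 'latent'")
    return ForecastResult(
        horizons=(1,),
        log_mean=mu,
        log_sd=np.sqrt(var)[None, :],
        target=target,
    )


def kalman_forecast(
    fit: FittedModel, request: ForecastRequest, target: str = "measurement"
) -> ForecastResult:
    """Forecast by Kalman filtering the prior measurements.

    Missing positions at a prior visit are handled by row selection in the
    update step.  The filtered state is propagated to each horizon; on the
    measurement scale the error variance is added to the predictive
    variance.  Numerically identical to exact conditioning of the joint
    Gaussian on the observed entries (see :func:`conditional_oracle`).
    """
    if target not in ("measurement", "latent"):
        raise RequestError("target must be 'measurement' or 'latent'")
    request.check_spacing(fit.visit_spacing_years)
    p = fit.params
    Sigma, rho, s2 = p.sigma_spatial, p.rho, p.sigma2_meas
    T_obs = request.n_observed
    last = max(request.horizons)
    mu = _means_by_visit(fit, request.covariates, last)

    m = mu[0].copy()
    P = Sigma.copy()
    prior_lm = np.empty((T_obs, N_POSITIONS))
    prior_ls = np.empty((T_obs, N_POSITIONS))
    with np.errstate(invalid="ignore"):
        logy = np.log(request.prior_measurements)
    for t in range(T_obs):
        # one-step predictive for the incoming measurement (flagging basis)
        prior_lm[t] = m
        prior_ls[t] = np.sqrt(np.maximum(np.diag(P) + s2, 0.0))
        obs = np.flatnonzero(~np.isnan(logy[t]))
        if obs.size:
            S = P[np.ix_(obs, obs)] + np.diag(s2[obs])
            K = np.linalg.solve(S, P[obs, :]).T          # (9, n_obs)
            m = m + K @ (logy[t, obs] - m[obs])
            P = P - K @ P[obs, :]
            P = 0.5 * (P + P.T)
        if t + 1 < last:
            m = mu[t + 1] + rho * (m - mu[t])
            P = rho**2 * P + (1.0 - rho**2) * Sigma
    # after the loop the state refers to visit T_obs + 1 (or visit 1 if no
    # priors); propagate to each horizon
    state_visit = T_obs + 1
    H = len(request.horizons)
    log_mean = np.empty((H, N_POSITIONS))
    log_var = np.empty((H, N_POSITIONS))
    for i, h in enumerate(request.horizons):
        k = h - state_visit
        r2k = rho ** (2 * k)
        mh = mu[h - 1] + rho**k * (m - mu[state_visit - 1])
        Ph_diag = r2k * np.diag(P) + (1.0 - r2k) * np.diag(Sigma)
        log_mean[i] = mh
        log_var[i] = Ph_diag + (s2 if target == "measurement" else 0.0)

    prior_flags = None
    if T_obs:
        lo = prior_lm - Z_95 * prior_ls
        hi = prior_lm + Z_95 * prior_ls
        with np.errstate(invalid="ignore"):
            prior_flags = (logy < lo) | (logy > hi)
        prior_flags[np.isnan(logy)] = False
    return ForecastResult(
        horizons=request.horizons,
        log_mean=log_mean,
        log_sd=np.sqrt(log_var),
        target=target,
        prior_log_mean=prior_lm if T_obs else None,
        prior_log_sd=prior_ls if T_obs else None,
        prior_flags=prior_flags,
    )


def conditional_oracle(
    fit: FittedModel, request: ForecastRequest, target: str = "measurement"
) -> ForecastResult:
    """Brute-force forecast by dense multivariate-normal conditioning.

    Builds the joint mean and covariance of all visits up to the last
    horizon and applies the Schur-complement formula on the observed
    entries.  Test oracle for :func:`kalman_forecast`; limited to small
    stacked dimensions.
    """
    if target not in ("measurement", "latent"):
        raise RequestError("target must be 'measurement' or 'latent'")
    last = max(request.horizons)
    if last > _ORACLE_MAX_VISITS:
        raise RequestError(
            f"oracle limited to {_ORACLE_MAX_VISITS} stacked visits, got {last}"
        )
    p = fit.params
    mu = mean_vector(p, request.covariates, last)  # flat, length 9*last
    Gam = marginal_covariance(p, last)

    T_obs = request.n_observed
    with np.errstate(invalid="ignore"):
        logy = np.log(request.prior_measurements).reshape(-1)
    obs = np.flatnonzero(~np.isnan(logy)) if T_obs else np.empty(0, dtype=int)

    fut = np.concatenate(
        [np.arange(N_POSITIONS) + (h - 1) * N_POSITIONS for h in request.horizons]
    )
    # joint covariance blocks; for the latent target the future block and
    # cross block exclude the measurement error (which is visit-local and
    # independent, so only the future-future diagonal changes)
    G_ff = Gam[np.ix_(fut, fut)].copy()
    if target == "latent":
        for i, gi in enumerate(fut):
            G_ff[i, i] -= p.sigma2_meas[gi % N_POSITIONS]
    if obs.size:
        G_oo = Gam[np.ix_(obs, obs)]
        # cross-covariance of a future value with an observed measurement
        # never contains the visit-local error term (horizons > observed
        # visits), so the block is the same for both targets
        G_fo = Gam[np.ix_(fut, obs)]
        sol = np.linalg.solve(G_oo, (logy[obs] - mu[obs]))
        cmean = mu[fut] + G_fo @ sol
        ccov = G_ff - G_fo @ np.linalg.solve(G_oo, G_fo.T)
    else:
        cmean = mu[fut]
        ccov = G_ff
    H = len(request.horizons)
    return ForecastResult(
        horizons=request.horizons,
        log_mean=cmean.reshape(H, N_POSITIONS),
        log_sd=np.sqrt(np.maximum(np.diag(ccov), 0.0)).reshape(H, N_POSITIONS),
        target=target,
    )


def flag_outside_limits(
    result: ForecastResult, measured_mm: np.ndarray
) -> np.ndarray:
    """Flag measurements strictly outside the 95% prediction limits.

    A value exactly on a limit is *not* flagged (strict inequality).
    NaN (unmeasured) entries are never flagged.
    """
    m = np.asarray(measured_mm, dtype=float).reshape(result.log_mean.shape)
    with np.errstate(invalid="ignore"):
        flags = (m < result.lower_mm) | (m > result.upper_mm)
    flags[np.isnan(m)] = False
    return flags


def extend_trajectory(
    traj: CovariateTrajectory, to_visit: int, visit_spacing_years: float
) -> CovariateTrajectory:
    """Project a covariate trajectory forward to ``to_visit`` visits.

    Default projection: carry the last observed value forward, advancing
    age deterministically by the visit spacing and ERT duration likewise
    for subjects on ERT (nonzero last duration).
    """
    T = traj.n_visits
    if to_visit <= T:
        return traj
    extra = to_visit - T
    values = {}
    for name, v in traj.values.items():
        last = v[-1]
        if name == "age":
            proj = last + visit_spacing_years * np.arange(1, extra + 1)
        elif name == "ert_duration" and last > 0:
            proj = last + visit_spacing_years * np.arange(1, extra + 1)
        else:
            proj = np.full(extra, last)
        values[name] = np.concatenate([v, proj])
    return CovariateTrajectory(subject_id=traj.subject_id, values=values)
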