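"""Mean and covariance structure of the model, and the observed-data
likelihood machinery.

The stacked measurement vector of one subject is ordered *visit-major*:
visit 1 positions 1..9, then visit 2, ...  Under that convention the
marginal covariance of the full 9T-vector is

    Gamma = R(rho) (x) Sigma + I_T (x) diag(sigma2_meas),

with ``R(rho)[t, s] = rho^|t-s|`` the AR(1) correlation over visits,
``Sigma`` the unstructured 9x9 between-position covariance, and the last
term the independent position-specific measurement error.

Subjects with missing visits or positions contribute the corresponding
sub-vector: rows/columns of ``Gamma`` are subset to the observed entries
(marginalization, never imputation).  For speed, subjects are grouped by
missingness pattern so each distinct sub-matrix is factorized once.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve, cholesky, solve_triangular

from .dataset import CohortDataset, CovariateTrajectory
from .errors import DataError, ParameterError, SpecificationError
from .params import ModelParameters, ModelSpec
from .positions import N_POSITIONS

logger = logging.getLogger(__name__)

_LOG2PI = np.log(2.0 * np.pi)


def ar1_correlation(rho: float, n_visits: int) -> np.ndarray:
    """AR(1) correlation matrix ``R[t, s] = rho^|t-s|`` over visits."""
    if abs(rho) >= 1:
        raise ParameterError(f"|rho| must be < 1, got {rho}")
    lags = np.abs(np.subtract.outer(np.arange(n_visits), np.arange(n_visits)))
    return rho ** lags


def ar1_correlation_drho(rho: float, n_visits: int) -> np.ndarray:
    """Elementwise derivative of :func:`ar1_correlation` with respect to rho."""
    lags = np.abs(np.subtract.outer(np.arange(n_visits), np.arange(n_visits)))
    with np.errstate(divide="ignore", invalid="ignore"):
        d = lags * rho ** np.maximum(lags - 1, 0)
    d[lags == 0] = 0.0
    return d.astype(float)


def mean_vector(
    params: ModelParameters, traj: CovariateTrajectory, n_visits: int
) -> np.ndarray:
    """Model mean of the stacked log-diameter vector (length 9*n_visits).

    Entry for (visit t, position j) is ``x_t' beta_j``; visit-major order.
    """
    if traj.n_visits < n_visits:
        raise SpecificationError(
            f"trajectory has {traj.n_visits} visits, {n_visits} requested"
        )
    X = traj.design_matrix(params.covariates)[:n_visits]  # (T, p)
    if np.any(np.isnan(X)):
        raise SpecificationError("covariates contain NaN over the requested visits")
    return (X @ params.beta.T).reshape(-1)  # (T, 9) -> visit-major flat


def marginal_covariance(params: ModelParameters, n_visits: int) -> np.ndarray:
    """Marginal covariance ``R(rho) (x) Sigma + I (x) diag(sigma2)``.

    Returns the (9T, 9T) covariance of the stacked visit-major vector.
    """
    R = ar1_correlation(params.rho, n_visits)
    return np.kron(R, params.sigma_spatial) + np.kron(
        np.eye(n_visits), np.diag(params.sigma2_meas)
    )


# ---------------------------------------------------------------------------
# Stacked design / pattern-grouped likelihood
# ---------------------------------------------------------------------------


@dataclass
class _PatternGroup:
    idx: np.ndarray          # observed flat indices into the 9T grid
    subjects: np.ndarray     # subject row numbers in this group
    Y: np.ndarray            # (m, d) observed log-diameters
    Z: np.ndarray            # (m, d, q) fixed-effect design rows


@dataclass
class GLSResult:
    """Generalized-least-squares fixed effects at given covariance parameters."""

    theta: np.ndarray        # packed fixed-effect estimates (q,)
    covariance: np.ndarray   # (q, q) coefficient covariance (M^{-1})
    beta: np.ndarray         # (9, p) expanded coefficient matrix
    names: list[str]


@dataclass
class _Profile:
    """Internal result of one likelihood evaluation."""

    loglik: float
    loglik_ml: float
    theta: np.ndarray
    M: np.ndarray
    grad: np.ndarray | None = None
    fisher: np.ndarray | None = None


def build_full_design(X: np.ndarray, spec: ModelSpec) -> np.ndarray:
    """Expand a (T, p) per-visit design into the (T*9, q) stacked design.

    Row (t, j) holds each covariate's visit-t value in the column of its
    position-j slope (or its single shared-slope column).
    """
    T = X.shape[0]
    q = spec.n_fixed
    Z = np.zeros((T, N_POSITIONS, q))
    slices = spec.theta_slices()
    for c_idx, c in enumerate(spec.all_covariates):
        sl = slices[c]
        if sl.stop - sl.start == 1:  # shared slope
            Z[:, :, sl.start] = X[:, c_idx][:, None]
        else:
            j = np.arange(N_POSITIONS)
            Z[:, j, sl.start + j] = X[:, c_idx][:, None]
    return Z.reshape(T * N_POSITIONS, q)


class CohortEvaluator:
    """Pattern-grouped evaluator of the observed-data (restricted) likelihood.

    Precomputes, per subject, the observed sub-vector and design rows, and
    groups subjects by missingness pattern so every likelihood evaluation
    factorizes each distinct observed covariance sub-matrix exactly once.
    """

    def __init__(self, dataset: CohortDataset, spec: ModelSpec, check_rank: bool = True):
        self.spec = spec
        self.n_visits = dataset.n_visits
        self.dim = dataset.n_visits * N_POSITIONS
        self.q = spec.n_fixed
        mask_flat = dataset.mask.reshape(dataset.n_subjects, -1)
        logy = dataset.log_diam.reshape(dataset.n_subjects, -1)

        groups: dict[tuple, list[int]] = {}
        skipped = []
        for i in range(dataset.n_subjects):
            key = tuple(np.flatnonzero(mask_flat[i]))
            if not key:
                skipped.append(dataset.subject_ids[i])
                continue
            groups.setdefault(key, []).append(i)
        if skipped:
            msg = f"skipping {len(skipped)} subject(s) with no observations: {skipped[:5]}"
            logger.warning(msg)
            warnings.warn(msg, stacklevel=2)
        if not groups:
            raise DataError("no observed measurements in the dataset")

        # Per-visit design matrices for all subjects
        p = len(spec.all_covariates)
        Xall = np.empty((dataset.n_subjects, dataset.n_visits, p))
        Xall[:, :, 0] = 1.0
        for c_idx, c in enumerate(spec.all_covariates[1:], start=1):
            if c not in dataset.covariates:
                raise SpecificationError(f"covariate {c!r} missing from dataset")
            Xall[:, :, c_idx] = dataset.covariates[c]

        self.groups: list[_PatternGroup] = []
        self.n_obs = 0
        for key, subj in groups.items():
            idx = np.asarray(key)
            subj = np.asarray(subj)
            Y = logy[np.ix_(subj, idx)]
            if not np.all(np.isfinite(Y)):
                raise DataError("non-finite log-diameter among observed entries")
            Z = np.stack(
                [build_full_design(Xall[i], spec)[idx] for i in subj]
            )
            if np.any(np.isnan(Z)):
                raise DataError(
                    "covariate missing (NaN) at an observed measurement"
                )
            self.groups.append(_PatternGroup(idx=idx, subjects=subj, Y=Y, Z=Z))
            self.n_obs += Y.size

        if check_rank:
            self._check_rank()

    def _check_rank(self) -> None:
        ZtZ = np.zeros((self.q, self.q))
        for g in self.groups:
            Zm = g.Z.reshape(-1, self.q)
            ZtZ += Zm.T @ Zm
        # scale-invariant rank check via correlation-like normalization
        d = np.sqrt(np.diag(ZtZ))
        if np.any(d == 0):
            bad = [n for n, di in zip(self.spec.theta_names(), d) if di == 0]
            raise SpecificationError(f"design columns identically zero: {bad}")
        C = ZtZ / np.outer(d, d)
        eigval, eigvec = np.linalg.eigh(C)
        if eigval[0] < 1e-10:
            w = np.abs(eigvec[:, 0])
            bad = [
                n for n, wi in zip(self.spec.theta_names(), w) if wi > 0.1 * w.max()
            ]
            raise SpecificationError(
                f"rank-deficient fixed-effect design; collinear columns: {bad}"
            )

    # -- core evaluation --------------------------------------------------
    def profile(
        self,
        Sigma: np.ndarray,
        rho: float,
        sigma2: np.ndarray,
        criterion: str = "reml",
        A_stack: np.ndarray | None = None,
        want_fisher: bool = False,
    ) -> _Profile:
        """Profiled log-likelihood at the given covariance parameters.

        The fixed effects are profiled out by GLS.  If ``A_stack`` (K, 9T,
        9T) of derivative directions dGamma/dtheta_k is supplied, the exact
        gradient of the profiled criterion is returned; ``want_fisher`` adds
        the expected-information matrix in the same directions.
        """
        if criterion not in ("reml", "ml"):
            raise ValueError("criterion must be 'reml' or 'ml'")
        T = self.n_visits
        R = ar1_correlation(rho, T)
        Gam = np.kron(R, Sigma) + np.kron(np.eye(T), np.diag(sigma2))

        q = self.q
        M = np.zeros((q, q))
        b = np.zeros(q)
        logdet = 0.0
        cache = []
        for g in self.groups:
            d = g.idx.size
            m = g.subjects.size
            Gp = Gam[np.ix_(g.idx, g.idx)]
            Lp = cholesky(Gp, lower=True)
            logdet += m * 2.0 * np.sum(np.log(np.diag(Lp)))
            Ly = solve_triangular(Lp, g.Y.T, lower=True)            # (d, m)
            LZ = solve_triangular(
                Lp, g.Z.transpose(1, 0, 2).reshape(d, m * q), lower=True
            ).reshape(d, m, q)
            M += np.einsum("dmq,dmr->qr", LZ, LZ, optimize=True)
            b += np.einsum("dmq,dm->q", LZ, Ly, optimize=True)
            cache.append((g, Lp, Ly, LZ))

        cM = cho_factor(M, lower=True)
        theta = cho_solve(cM, b)
        rss = 0.0
        resids = []
        for g, Lp, Ly, LZ in cache:
            e = Ly - np.einsum("dmq,q->dm", LZ, theta, optimize=True)
            rss += float(np.sum(e * e))
            resids.append(e)

        ml = -0.5 * (self.n_obs * _LOG2PI + logdet + rss)
        if criterion == "reml":
            logdetM = 2.0 * np.sum(np.log(np.diag(cM[0])))
            value = ml + 0.5 * q * _LOG2PI - 0.5 * logdetM
        else:
            value = ml

        grad = fisher = None
        if A_stack is not None or want_fisher:
            Minv = cho_solve(cM, np.eye(q)) if criterion == "reml" else None
            E = np.zeros((self.dim, self.dim))
            fisher_acc = (
                np.zeros((A_stack.shape[0], A_stack.shape[0]))
                if want_fisher and A_stack is not None
                else None
            )
            for (g, Lp, Ly, LZ), e in zip(cache, resids):
                d = g.idx.size
                m = g.subjects.size
                ix = np.ix_(g.idx, g.idx)
                Ginv = cho_solve((Lp, True), np.eye(d))
                U = solve_triangular(Lp, e, trans="T", lower=True)   # (d, m)
                Ep = m * Ginv - U @ U.T
                if criterion == "reml":
                    W = solve_triangular(
                        Lp, LZ.reshape(d, m * q), trans="T", lower=True
                    ).reshape(d, m, q)
                    WM = np.einsum("dmq,qr->dmr", W, Minv, optimize=True)
                    Ep -= np.einsum("dmq,emq->de", WM, W, optimize=True)
                E[ix] += Ep
                if fisher_acc is not None:
                    Ap = A_stack[:, g.idx[:, None], g.idx[None, :]]
                    B = np.matmul(Ginv, Ap)                          # (K, d, d)
                    fisher_acc += 0.5 * m * np.einsum(
                        "kij,lji->kl", B, B, optimize=True
                    )
            if A_stack is not None:
                grad = -0.5 * np.einsum("kij,ij->k", A_stack, E, optimize=True)
            fisher = fisher_acc

        return _Profile(
            loglik=float(value), loglik_ml=float(ml), theta=theta, M=M,
            grad=grad, fisher=fisher,
        )

    def beta_covariance(self, M: np.ndarray) -> np.ndarray:
        return cho_solve(cho_factor(M, lower=True), np.eye(self.q))


# ---------------------------------------------------------------------------
# Public likelihood functions
# ---------------------------------------------------------------------------


def observed_loglik(
    params: ModelParameters, dataset: CohortDataset, spec: ModelSpec
) -> float:
    """Observed-data log-likelihood at fully specified parameters.

    Sum over subjects of the multivariate-normal log-density of the observed
    log-diameter sub-vector; missing entries are marginalized out.
    """
    _check_spec_params(params, spec)
    Gam = marginal_covariance(params, dataset.n_visits)
    mask_flat = dataset.mask.reshape(dataset.n_subjects, -1)
    logy = dataset.log_diam.reshape(dataset.n_subjects, -1)

    p = len(params.covariates)
    Xall = np.empty((dataset.n_subjects, dataset.n_visits, p))
    Xall[:, :, 0] = 1.0
    for c_idx, c in enumerate(params.covariates[1:], start=1):
        if c not in dataset.covariates:
            raise SpecificationError(f"covariate {c!r} missing from dataset")
        Xall[:, :, c_idx] = dataset.covariates[c]
    means = np.einsum("ntp,jp->ntj", Xall, params.beta).reshape(
        dataset.n_subjects, -1
    )

    groups: dict[tuple, list[int]] = {}
    for i in range(dataset.n_subjects):
        key = tuple(np.flatnonzero(mask_flat[i]))
        if not key:
            msg = f"subject {dataset.subject_ids[i]!r} has no observations; skipped"
            logger.warning(msg)
            warnings.warn(msg, stacklevel=2)
            continue
        groups.setdefault(key, []).append(i)

    total = 0.0
    for key, subj in groups.items():
        idx = np.asarray(key)
        d = idx.size
        m = len(subj)
        r = logy[np.ix_(subj, idx)] - means[np.ix_(subj, idx)]
        if not np.all(np.isfinite(r)):
            raise DataError("non-finite residual among observed entries")
        Lp = cholesky(Gam[np.ix_(idx, idx)], lower=True)
        e = solve_triangular(Lp, r.T, lower=True)
        total += -0.5 * (
            m * d * _LOG2PI
            + m * 2.0 * np.sum(np.log(np.diag(Lp)))
            + float(np.sum(e * e))
        )
    return total


def reml_loglik(
    params: ModelParameters, dataset: CohortDataset, spec: ModelSpec
) -> float:
    """Restricted log-likelihood at the covariance part of ``params``.

    The fixed effects are profiled out by GLS; includes the
    ``-1/2 log|sum_i Z_i' Gamma_i^{-1} Z_i|`` adjustment and the
    ``(N - q)/2 log 2pi`` constant.
    """
    ev = CohortEvaluator(dataset, spec)
    return ev.profile(
        params.sigma_spatial, params.rho, params.sigma2_meas, criterion="reml"
    ).loglik


def gls_beta(
    params: ModelParameters, dataset: CohortDataset, spec: ModelSpec
) -> GLSResult:
    """GLS fixed effects and their covariance at given covariance parameters.

    Only the covariance components of ``params`` are used; ``params.beta``
    is ignored.
    """
    ev = CohortEvaluator(dataset, spec)
    prof = ev.profile(
        params.sigma_spatial, params.rho, params.sigma2_meas, criterion="ml"
    )
    cov = ev.beta_covariance(prof.M)
    return GLSResult(
        theta=prof.theta,
        covariance=cov,
        beta=spec.theta_to_beta(prof.theta),
        names=spec.theta_names(),
    )


def _check_spec_params(params: ModelParameters, spec: ModelSpec) -> None:
    if params.covariates != spec.all_covariates:
        raise SpecificationError(
            "parameter covariates do not match the model spec: "
            f"{params.covariates} vs {spec.all_covariates}"
        )
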