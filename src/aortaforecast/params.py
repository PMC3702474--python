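"""Parameter space of the spatio-temporal aortic-diameter model.

The model is a multivariate linear mixed model on the natural logarithm of
aortic diameter (mm).  For subject *i*, visit *t* and position *j*,

    log d_{itj} = x_{it}' beta_j + e_{itj},

where the residual field combines (i) an unstructured 9x9 spatial covariance
``Sigma`` between positions, (ii) a first-order autoregression with
coefficient ``rho`` across equally spaced visits, and (iii) independent
position-specific measurement errors ``sigma2_meas``:

    Cov(e_{itj}, e_{isk}) = rho^{|t-s|} Sigma_{jk} + 1{t=s, j=k} sigma2_j.

The first two terms form a Kronecker product R(rho) (x) Sigma over the
stacked visit-major vector.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import ParameterError, SpecificationError
from .positions import N_POSITIONS, POSITIONS

INTERCEPT = "intercept"


def _as_matrix(x, shape, name: str) -> np.ndarray:
    a = np.asarray(x, dtype=float)
    if a.shape != shape:
        raise ParameterError(f"{name} must have shape {shape}, got {a.shape}")
    return a


@dataclass(frozen=True)
class ModelParameters:
    """Complete parameter set: fixed effects plus covariance components.

    Parameters
    ----------
    covariates
        Covariate names, starting with ``"intercept"``; columns of ``beta``.
    beta
        (9, p) matrix of log-scale coefficients, one row per aortic position.
    sigma_spatial
        9x9 symmetric positive semi-definite between-position covariance
        (strictly positive definite is required for likelihood evaluation;
        the semi-definite boundary is admitted for noise-free simulation).
    rho
        Temporal autocorrelation per visit interval, ``|rho| < 1``.
    sigma2_meas
        Nine non-negative measurement-error variances (log scale).
    """

    covariates: tuple[str, ...]
    beta: np.ndarray
    sigma_spatial: np.ndarray
    rho: float
    sigma2_meas: np.ndarray

    def __post_init__(self):
        covs = tuple(self.covariates)
        if not covs or covs[0] != INTERCEPT:
            raise ParameterError("covariates must start with 'intercept'")
        object.__setattr__(self, "covariates", covs)
        p = len(covs)
        object.__setattr__(
            self, "beta", _as_matrix(self.beta, (N_POSITIONS, p), "beta")
        )
        sig = _as_matrix(
            self.sigma_spatial, (N_POSITIONS, N_POSITIONS), "sigma_spatial"
        )
        if not np.allclose(sig, sig.T, atol=1e-10):
            raise ParameterError("sigma_spatial must be symmetric")
        sig = 0.5 * (sig + sig.T)
        w = np.linalg.eigvalsh(sig)
        if w[0] < -1e-10 * max(1.0, w[-1]):
            raise ParameterError("sigma_spatial must be positive semi-definite")
        object.__setattr__(self, "sigma_spatial", sig)
        if not np.isfinite(self.rho) or abs(self.rho) >= 1.0:
            raise ParameterError(f"rho must satisfy |rho| < 1, got {self.rho}")
        s2 = np.asarray(self.sigma2_meas, dtype=float).reshape(-1)
        if s2.shape != (N_POSITIONS,):
            raise ParameterError("sigma2_meas must have length 9")
        if np.any(s2 < 0):
            raise ParameterError("sigma2_meas must be non-negative")
        object.__setattr__(self, "sigma2_meas", s2)

    @property
    def n_covariates(self) -> int:
        return len(self.covariates)

    def coefficient(self, covariate: str, position: str | int) -> float:
        """Single beta entry by covariate name and position label/index."""
        j = position if isinstance(position, int) else POSITIONS.index(position)
        try:
            c = self.covariates.index(covariate)
        except ValueError:
            raise SpecificationError(f"covariate {covariate!r} not in model") from None
        return float(self.beta[j, c])

    # ---- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "covariates": list(self.covariates),
            "positions": list(POSITIONS),
            "beta": self.beta.tolist(),
            "sigma_spatial": self.sigma_spatial.tolist(),
            "rho": float(self.rho),
            "sigma2_meas": self.sigma2_meas.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParameters":
        if tuple(d.get("positions", POSITIONS)) != POSITIONS:
            raise ParameterError("position grid does not match this package's order")
        return cls(
            covariates=tuple(d["covariates"]),
            beta=np.asarray(d["beta"], dtype=float),
            sigma_spatial=np.asarray(d["sigma_spatial"], dtype=float),
            rho=float(d["rho"]),
            sigma2_meas=np.asarray(d["sigma2_meas"], dtype=float),
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "ModelParameters":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass(frozen=True)
class ModelSpec:
    """Fixed-effect specification.

    ``covariates`` lists the risk factors entering the mean (the intercept is
    implicit and always position-specific).  Covariates named in ``shared``
    get one slope common to all nine positions; all others get nine
    position-specific slopes.  The response is the natural log of diameter
    in mm.
    """

    covariates: tuple[str, ...]
    shared: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self):
        covs = tuple(self.covariates)
        if len(covs) == 0:
            raise SpecificationError("at least one covariate is required")
        if len(set(covs)) != len(covs):
            raise SpecificationError("duplicate covariate names")
        if INTERCEPT in covs:
            raise SpecificationError("intercept is implicit; do not list it")
        object.__setattr__(self, "covariates", covs)
        shared = frozenset(self.shared)
        unknown = shared - set(covs)
        if unknown:
            raise SpecificationError(
                f"shared covariates not in the model: {sorted(unknown)}"
            )
        object.__setattr__(self, "shared", shared)

    @property
    def all_covariates(self) -> tuple[str, ...]:
        """Covariate names including the implicit intercept, design order."""
        return (INTERCEPT,) + self.covariates

    @property
    def n_fixed(self) -> int:
        """Number of free fixed-effect parameters."""
        n = N_POSITIONS  # intercept, always position-specific
        for c in self.covariates:
            n += 1 if c in self.shared else N_POSITIONS
        return n

    def theta_slices(self) -> dict[str, slice]:
        """Map covariate name -> slice into the packed fixed-effect vector."""
        out: dict[str, slice] = {}
        k = 0
        for c in self.all_covariates:
            w = 1 if c in self.shared else N_POSITIONS
            out[c] = slice(k, k + w)
            k += w
        return out

    def theta_to_beta(self, theta: np.ndarray) -> np.ndarray:
        """Expand the packed fixed-effect vector to the (9, p) beta matrix."""
        theta = np.asarray(theta, dtype=float).reshape(-1)
        if theta.shape != (self.n_fixed,):
            raise SpecificationError(
                f"theta must have length {self.n_fixed}, got {theta.shape}"
            )
        beta = np.empty((N_POSITIONS, len(self.all_covariates)))
        for c_idx, (c, sl) in enumerate(self.theta_slices().items()):
            block = theta[sl]
            beta[:, c_idx] = block if block.size == N_POSITIONS else block[0]
        return beta

    def beta_to_theta(self, beta: np.ndarray) -> np.ndarray:
        """Pack a (9, p) beta matrix; shared covariates use the mean slope."""
        beta = _as_matrix(beta, (N_POSITIONS, len(self.all_covariates)), "beta")
        parts = []
        for c_idx, c in enumerate(self.all_covariates):
            col = beta[:, c_idx]
            parts.append(np.array([col.mean()]) if c in self.shared else col)
        return np.concatenate(parts)

    def theta_names(self) -> list[str]:
        """Names of the packed fixed-effect parameters, design order."""
        names: list[str] = []
        for c in self.all_covariates:
            if c in self.shared:
                names.append(f"{c}(shared)")
            else:
                names.extend(f"{c}:{pos}" for pos in POSITIONS)
        return names

    def with_shared(self, covariate: str) -> "ModelSpec":
        """Copy of the spec with one covariate constrained to a common slope."""
        if covariate not in self.covariates:
            raise SpecificationError(f"covariate {covariate!r} not in model")
        return ModelSpec(self.covariates, self.shared | {covariate})

    def to_dict(self) -> dict:
        return {"covariates": list(self.covariates), "shared": sorted(self.shared)}

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        return cls(tuple(d["covariates"]), frozenset(d.get("shared", ())))


def make_parameters(
    spec: ModelSpec,
    beta: np.ndarray,
    sigma_spatial: np.ndarray,
    rho: float,
    sigma2_meas: Sequence[float] | np.ndarray,
) -> ModelParameters:
    """Build :class:`ModelParameters` with covariate names from a spec."""
    return ModelParameters(
        covariates=spec.all_covariates,
        beta=beta,
        sigma_spatial=sigma_spatial,
        rho=rho,
        sigma2_meas=np.asarray(sigma2_meas, dtype=float),
    )
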