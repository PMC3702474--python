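"""In-memory containers for cohort measurement data.

A cohort is a balanced grid of subjects x visits x 9 positions with
missingness: a visit a subject did not attend has no diameters (and no
visit-level covariates); individual positions may also be missing within an
attended visit.  Visits are assumed equally spaced in time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DataError
from .positions import N_POSITIONS, POSITIONS

#: Covariates that may change between visits.
TIME_VARYING = ("age", "diastolic_abp", "bsa", "ert_duration", "antihypertensive")
#: Covariates fixed over the study.
TIME_CONSTANT = ("bav", "coarctation", "karyotype_45x", "elongated_arch")
#: Default full covariate set, order matching the cohesive model.
DEFAULT_COVARIATES = (
    "coarctation",
    "age",
    "bav",
    "antihypertensive",
    "diastolic_abp",
    "bsa",
    "ert_duration",
    "karyotype_45x",
    "elongated_arch",
)


@dataclass
class CovariateTrajectory:
    """One subject's covariate values over visits.

    ``values[name]`` is a float array over visits; time-constant covariates
    are stored replicated per visit.
    """

    subject_id: str
    values: dict[str, np.ndarray]

    def __post_init__(self):
        self.values = {k: np.asarray(v, dtype=float) for k, v in self.values.items()}
        lengths = {v.shape for v in self.values.values()}
        if len(lengths) > 1:
            raise DataError("all covariate arrays must share the same length")

    @property
    def n_visits(self) -> int:
        return next(iter(self.values.values())).shape[0]

    def design_matrix(self, covariates: tuple[str, ...]) -> np.ndarray:
        """(n_visits, p) design matrix with a leading intercept column.

        ``covariates`` must start with ``"intercept"`` (the convention of
        :class:`~aortaforecast.params.ModelParameters.covariates`).
        """
        cols = [np.ones(self.n_visits)]
        for name in covariates:
            if name == "intercept":
                continue
            if name not in self.values:
                raise DataError(f"covariate {name!r} missing from trajectory")
            cols.append(self.values[name])
        return np.column_stack(cols)


@dataclass
class CohortDataset:
    """Cohort of aortic-diameter measurements on the 9-position grid.

    Attributes
    ----------
    subject_ids
        Length-n sequence of identifiers.
    diam_mm
        (n, T, 9) diameters in mm; NaN marks a missing measurement.
    covariates
        Mapping covariate name -> (n, T) array; NaN where the visit is
        unobserved.
    visit_spacing_years
        Constant spacing between consecutive visits.
    """

    subject_ids: list[str]
    diam_mm: np.ndarray
    covariates: dict[str, np.ndarray]
    visit_spacing_years: float
    positions: tuple[str, ...] = field(default=POSITIONS)

    def __post_init__(self):
        self.diam_mm = np.asarray(self.diam_mm, dtype=float)
        n, T, J = self.diam_mm.shape
        if J != N_POSITIONS:
            raise DataError(f"expected {N_POSITIONS} positions, got {J}")
        if len(self.subject_ids) != n:
            raise DataError("subject_ids length does not match diam_mm")
        if tuple(self.positions) != POSITIONS:
            raise DataError("position grid must match the canonical order")
        with np.errstate(invalid="ignore"):
            if np.any(self.diam_mm <= 0):
                raise DataError("diameters must be positive")
        if np.any(np.isinf(self.diam_mm)):
            raise DataError("diameters must be finite")
        for k, v in self.covariates.items():
            v = np.asarray(v, dtype=float)
            if v.shape != (n, T):
                raise DataError(f"covariate {k!r} must have shape {(n, T)}")
            self.covariates[k] = v
        if self.visit_spacing_years <= 0:
            raise DataError("visit_spacing_years must be positive")

    @property
    def n_subjects(self) -> int:
        return self.diam_mm.shape[0]

    @property
    def n_visits(self) -> int:
        return self.diam_mm.shape[1]

    @property
    def mask(self) -> np.ndarray:
        """(n, T, 9) boolean: True where a measurement was made."""
        return ~np.isnan(self.diam_mm)

    @property
    def log_diam(self) -> np.ndarray:
        """(n, T, 9) natural-log diameters; NaN preserved."""
        with np.errstate(invalid="ignore"):
            return np.log(self.diam_mm)

    @property
    def years_from_baseline(self) -> np.ndarray:
        return np.arange(self.n_visits) * self.visit_spacing_years

    def visit_observed(self) -> np.ndarray:
        """(n, T) boolean: visit attended (any position measured)."""
        return self.mask.any(axis=2)

    def trajectory(self, i: int) -> CovariateTrajectory:
        """Covariate trajectory of subject ``i`` (NaN for missed visits)."""
        return CovariateTrajectory(
            subject_id=str(self.subject_ids[i]),
            values={k: v[i].copy() for k, v in self.covariates.items()},
        )

    def subset_subjects(self, idx) -> "CohortDataset":
        idx = np.asarray(idx)
        return CohortDataset(
            subject_ids=[self.subject_ids[i] for i in idx],
            diam_mm=self.diam_mm[idx].copy(),
            covariates={k: v[idx].copy() for k, v in self.covariates.items()},
            visit_spacing_years=self.visit_spacing_years,
        )

    def equals(self, other: "CohortDataset") -> bool:
        if self.subject_ids != other.subject_ids:
            return False
        if self.visit_spacing_years != other.visit_spacing_years:
            return False
        if not _nan_equal(self.diam_mm, other.diam_mm):
            return False
        if set(self.covariates) != set(other.covariates):
            return False
        return all(_nan_equal(v, other.covariates[k]) for k, v in self.covariates.items())


def _nan_equal(a: np.ndarray, b: np.ndarray) -> bool:
    return a.shape == b.shape and np.array_equal(a, b, equal_nan=True)
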