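"""Reporting artifacts from a fitted model.

Turns estimates on the log-diameter scale into the tables clinicians read:
per-position coefficients with Wald 95% confidence intervals, effect sizes
as the percentage change in diameter per reporting unit
(``100 (exp(beta u) - 1)``), joint per-variable Wald chi-square tests, and
the likelihood-ratio test of whether a risk factor acts uniformly along the
aorta or with position-dependent strength.

Tests are asymptotic (Wald chi-square, ML likelihood ratio); no
small-sample denominator-degree-of-freedom correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .dataset import CohortDataset
from .errors import SpecificationError
from .fitting import FitOptions, FittedModel, fit
from .params import ModelSpec
from .positions import N_POSITIONS, POSITIONS

Z_95 = 1.959963984540054

#: Reporting units: diastolic pressure per 10 mmHg, body surface area per
#: 0.1 m^2, everything else per its natural unit.
DEFAULT_UNIT_SCALES = {
    "diastolic_abp": 10.0,
    "bsa": 0.1,
}


@dataclass(frozen=True)
class UnitScale:
    """Covariate -> reporting-unit multiplier for percent-change columns."""

    scales: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_UNIT_SCALES)
    )

    def __post_init__(self):
        if any(v <= 0 for v in self.scales.values()):
            raise SpecificationError("unit multipliers must be positive")

    def unit(self, covariate: str) -> float:
        return self.scales.get(covariate, 1.0)


def percent_change(coefficient: float, unit: float = 1.0) -> float:
    """Percent change in diameter per ``unit`` increase of a covariate.

    On the log scale a coefficient ``b`` multiplies the diameter by
    ``exp(b u)`` per ``u`` units, i.e. ``100 (exp(b u) - 1)`` percent.
    """
    if unit <= 0:
        raise SpecificationError("unit must be positive")
    return 100.0 * np.expm1(coefficient * unit)


@dataclass
class TestResult:
    statistic: float
    df: int
    pvalue: float
    covariate: str
    kind: str  # "wald" or "lrt"


@dataclass
class EffectTable:
    """Per-position coefficient estimates, CIs and percent changes.

    ``table`` is a long DataFrame with one row per position x covariate;
    ``joint_tests`` maps covariate -> joint Wald test of all its
    coefficients being zero.
    """

    table: pd.DataFrame
    joint_tests: dict[str, TestResult]

    def to_csv(self, path) -> None:
        from .io import write_tagged_csv

        write_tagged_csv(self.table, path, "aortaforecast-effects/1")

    @classmethod
    def read_csv(cls, path) -> pd.DataFrame:
        from .io import read_tagged_csv

        return read_tagged_csv(path)

    def pivot(self, value: str = "estimate") -> pd.DataFrame:
        """Wide layout: positions as rows, covariates as columns."""
        wide = self.table.pivot(index="position", columns="covariate", values=value)
        return wide.reindex(POSITIONS)

    def text_report(self) -> str:
        lines = ["Per-position effects (log scale) with 95% CI and % change/unit", ""]
        for cov, grp in self.table.groupby("covariate", sort=False):
            jt = self.joint_tests.get(cov)
            head = f"{cov}"
            if jt is not None:
                head += f"   [joint chi2({jt.df}) = {jt.statistic:.2f}, p = {jt.pvalue:.3g}]"
            lines.append(head)
            for _, r in grp.iterrows():
                lines.append(
                    f"  {r['position']:<24s} {r['estimate']: .4f} "
                    f"({r['ci_lower']: .4f}, {r['ci_upper']: .4f})   "
                    f"{r['percent_change']: .2f}%/{r['unit']:g} unit"
                )
            lines.append("")
        return "\n".join(lines)


def coefficient_table(
    fit_result: FittedModel, scales: UnitScale = UnitScale()
) -> EffectTable:
    """Per-position estimates with Wald 95% CIs and percent-change columns.

    Shared-slope covariates appear with the same estimate at every position.
    Percent changes are computed from the unrounded estimates.
    """
    if not fit_result.converged:
        raise SpecificationError("coefficient table requires a converged fit")
    spec = fit_result.spec
    theta = fit_result.theta
    se = fit_result.theta_se()
    slices = spec.theta_slices()
    rows = []
    for cov in spec.all_covariates:
        sl = slices[cov]
        u = scales.unit(cov)
        est = theta[sl]
        s = se[sl]
        shared = est.size == 1
        for j, pos in enumerate(POSITIONS):
            e = est[0] if shared else est[j]
            si = s[0] if shared else s[j]
            rows.append(
                {
                    "covariate": cov,
                    "position": pos,
                    "estimate": e,
                    "se": si,
                    "ci_lower": e - Z_95 * si,
                    "ci_upper": e + Z_95 * si,
                    "unit": u,
                    "percent_change": percent_change(e, u),
                    "shared": shared,
                }
            )
    table = pd.DataFrame(rows)
    tests = {
        cov: joint_variable_test(fit_result, cov)
        for cov in spec.all_covariates
        if cov != "intercept"
    }
    return EffectTable(table=table, joint_tests=tests)


def joint_variable_test(fit_result: FittedModel, covariate: str) -> TestResult:
    """Wald chi-square test that all of a covariate's coefficients are zero.

    Uses the corresponding block of the coefficient covariance; df = 9 for
    a position-specific covariate, 1 for a shared slope.
    """
    spec = fit_result.spec
    if covariate not in spec.all_covariates:
        raise SpecificationError(f"covariate {covariate!r} not in the model")
    sl = spec.theta_slices()[covariate]
    b = fit_result.theta[sl]
    V = fit_result.beta_covariance[sl, sl]
    if not np.any(b):
        stat = 0.0
    elif b.size == 1:
        stat = float(b[0] ** 2 / V[0, 0]) if V[0, 0] > 0 else np.inf
    else:
        try:
            stat = float(b @ np.linalg.solve(V, b))
        except np.linalg.LinAlgError:
            # degenerate coefficient covariance (e.g. a zero-variance fit):
            # nonzero coefficients are then infinitely significant
            stat = np.inf
    df = b.size
    return TestResult(
        statistic=stat,
        df=df,
        pvalue=float(stats.chi2.sf(stat, df)) if stat > 0 else 1.0,
        covariate=covariate,
        kind="wald",
    )


def position_uniformity_test(
    dataset: CohortDataset,
    spec: ModelSpec,
    covariate: str,
    options: FitOptions = FitOptions(),
) -> TestResult:
    """Likelihood-ratio test: uniform vs position-dependent effect.

    Fits the full model (9 position-specific slopes for ``covariate``) and
    the nested shared-slope model, both by maximum likelihood (fixed-effect
    structures differ, so REML likelihoods are not comparable), and refers
    twice the log-likelihood difference to chi-square with 8 df.
    """
    if covariate not in spec.covariates:
        raise SpecificationError(f"covariate {covariate!r} not in the model")
    if covariate in spec.shared:
        raise SpecificationError(
            f"covariate {covariate!r} is already shared in the full spec"
        )
    ml_options = FitOptions(
        criterion="ml",
        tol=options.tol,
        max_iter=options.max_iter,
        restarts=options.restarts,
        seed=options.seed,
        perturb_scale=options.perturb_scale,
    )
    full = fit(dataset, spec, ml_options)
    shared = fit(dataset, spec.with_shared(covariate), ml_options)
    stat = max(2.0 * (full.loglik - shared.loglik), 0.0)
    df = N_POSITIONS - 1
    return TestResult(
        statistic=float(stat),
        df=df,
        pvalue=float(stats.chi2.sf(stat, df)) if stat > 0 else 1.0,
        covariate=covariate,
        kind="lrt",
    )
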