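"""Descriptive statistics: per-visit diameters and growth rates.

Growth rates are per-subject differences between two visits divided by the
elapsed years, summarized per position; visit-to-visit change is tested
with a paired t-test over subjects observed at both visits (complete-case).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .dataset import CohortDataset
from .errors import DataError
from .positions import POSITIONS


@dataclass
class DescriptiveSummary:
    """Per-visit means and growth-rate table."""

    per_visit: pd.DataFrame   # position, visit, n, mean_mm, sd_mm
    growth: pd.DataFrame      # position, n, rate mean/sd (mm/yr), paired t
    from_visit: int
    to_visit: int


def per_visit_summary(dataset: CohortDataset) -> pd.DataFrame:
    rows = []
    for t in range(dataset.n_visits):
        for j, pos in enumerate(POSITIONS):
            d = dataset.diam_mm[:, t, j]
            d = d[~np.isnan(d)]
            rows.append(
                {
                    "position": pos,
                    "visit": t + 1,
                    "n": d.size,
                    "mean_mm": d.mean() if d.size else np.nan,
                    "sd_mm": d.std(ddof=1) if d.size > 1 else np.nan,
                }
            )
    return pd.DataFrame(rows)


def growth_rates(
    dataset: CohortDataset, from_visit: int = 1, to_visit: int | None = None
) -> DescriptiveSummary:
    """Per-position growth rates (mm/year) between two visits.

    Only subjects measured at both visits contribute.  The paired t-test
    compares the raw diameters at the two visits; identical diameters give
    a statistic of exactly 0 and p = 1.
    """
    if to_visit is None:
        to_visit = dataset.n_visits
    if not 1 <= from_visit < to_visit <= dataset.n_visits:
        raise DataError(
            f"need 1 <= from_visit < to_visit <= {dataset.n_visits}, "
            f"got ({from_visit}, {to_visit})"
        )
    dt = (to_visit - from_visit) * dataset.visit_spacing_years
    rows = []
    for j, pos in enumerate(POSITIONS):
        a = dataset.diam_mm[:, from_visit - 1, j]
        b = dataset.diam_mm[:, to_visit - 1, j]
        ok = ~np.isnan(a) & ~np.isnan(b)
        n = int(ok.sum())
        if n < 2:
            raise DataError(
                f"fewer than 2 subjects observed at visits {from_visit} and "
                f"{to_visit} for position {pos}"
            )
        diff = b[ok] - a[ok]
        rate = diff / dt
        if np.allclose(diff, 0.0):
            t_stat, pval = 0.0, 1.0
        else:
            t_stat, pval = stats.ttest_rel(b[ok], a[ok])
        rows.append(
            {
                "position": pos,
                "n": n,
                "rate_mean_mm_per_yr": float(rate.mean()),
                "rate_sd_mm_per_yr": float(rate.std(ddof=1)),
                "paired_t": float(t_stat),
                "paired_p": float(pval),
            }
        )
    return DescriptiveSummary(
        per_visit=per_visit_summary(dataset),
        growth=pd.DataFrame(rows),
        from_visit=from_visit,
        to_visit=to_visit,
    )
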