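"""Long-format CSV I/O for cohort datasets.

One row per subject x visit x position for attended visits; a missed visit
simply has no rows.  A position not measured at an attended visit keeps its
row with an empty diameter so covariates and partial missingness survive a
round trip.  The first line is a schema/version tag comment that also
records the visit spacing.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import CohortDataset
from .errors import DataError
from .positions import N_POSITIONS, POSITIONS

SCHEMA_TAG = "aortaforecast-cohort-long/1"


def write_tagged_csv(frame: pd.DataFrame, path: str | Path, tag: str) -> None:
    """Write a DataFrame as CSV with a leading schema/version tag comment."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# schema={tag}\n")
        frame.to_csv(fh, index=False, float_format="%.17g")


def read_tagged_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", float_precision="round_trip")

_BASE_COLUMNS = [
    "subject_id",
    "visit_index",
    "years_from_baseline",
    "position",
    "diameter_mm",
]


def write_cohort_csv(dataset: CohortDataset, path: str | Path) -> None:
    """Write a cohort to long-format CSV (schema-tagged, lossless)."""
    cov_names = sorted(dataset.covariates)
    rows = []
    attended = dataset.visit_observed()
    years = dataset.years_from_baseline
    for i, sid in enumerate(dataset.subject_ids):
        for t in range(dataset.n_visits):
            if not attended[i, t]:
                continue
            for j, pos in enumerate(POSITIONS):
                d = dataset.diam_mm[i, t, j]
                row = {
                    "subject_id": sid,
                    "visit_index": t + 1,
                    "years_from_baseline": years[t],
                    "position": pos,
                    "diameter_mm": d if np.isfinite(d) else np.nan,
                }
                for c in cov_names:
                    row[c] = dataset.covariates[c][i, t]
                rows.append(row)
    frame = pd.DataFrame(rows, columns=_BASE_COLUMNS + cov_names)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(
            f"# schema={SCHEMA_TAG} spacing_years={dataset.visit_spacing_years!r} "
            f"n_visits={dataset.n_visits}\n"
        )
        # %.17g guarantees bit-exact float64 round trips
        frame.to_csv(fh, index=False, float_format="%.17g")


def read_cohort_csv(path: str | Path) -> CohortDataset:
    """Read a long-format cohort CSV written by :func:`write_cohort_csv`.

    Validates position labels, key uniqueness and positivity of diameters,
    reporting offending data row numbers (1-based, excluding header lines).
    """
    text = Path(path).read_text(encoding="utf-8")
    lines = text.splitlines()
    if not lines:
        raise DataError(f"{path}: empty file")
    spacing = None
    n_visits_tag = None
    if lines[0].startswith("#"):
        for tok in lines[0].split():
            if tok.startswith("spacing_years="):
                spacing = float(tok.split("=", 1)[1])
            if tok.startswith("n_visits="):
                n_visits_tag = int(tok.split("=", 1)[1])
        if f"schema={SCHEMA_TAG}" not in lines[0]:
            raise DataError(
                f"{path}: unrecognized schema tag; expected {SCHEMA_TAG}"
            )
    frame = pd.read_csv(_io.StringIO(text), comment="#", float_precision="round_trip")
    missing_cols = [c for c in _BASE_COLUMNS if c not in frame.columns]
    if missing_cols:
        raise DataError(f"{path}: missing required columns {missing_cols}")

    bad_pos = ~frame["position"].isin(POSITIONS)
    if bad_pos.any():
        rows = (frame.index[bad_pos] + 1).tolist()[:5]
        raise DataError(
            f"{path}: unknown position label(s) at data row(s) {rows}: "
            f"{sorted(frame.loc[bad_pos, 'position'].unique())[:3]}"
        )
    with np.errstate(invalid="ignore"):
        nonpos = frame["diameter_mm"].notna() & (frame["diameter_mm"] <= 0)
    if nonpos.any():
        rows = (frame.index[nonpos] + 1).tolist()[:5]
        raise DataError(f"{path}: non-positive diameter at data row(s) {rows}")
    dup = frame.duplicated(subset=["subject_id", "visit_index", "position"])
    if dup.any():
        rows = (frame.index[dup] + 1).tolist()[:5]
        raise DataError(
            f"{path}: duplicate (subject, visit, position) at data row(s) {rows}"
        )
    if (frame["visit_index"] < 1).any():
        raise DataError(f"{path}: visit_index must be >= 1")

    subjects = list(dict.fromkeys(frame["subject_id"].astype(str)))
    sidx = {s: i for i, s in enumerate(subjects)}
    n_visits = int(frame["visit_index"].max())
    if n_visits_tag is not None:
        n_visits = max(n_visits, n_visits_tag)
    if spacing is None:
        nz = frame[frame["visit_index"] > 1]
        if len(nz):
            spacing = float(
                (nz["years_from_baseline"] / (nz["visit_index"] - 1)).iloc[0]
            )
        else:
            raise DataError(
                f"{path}: visit spacing not recoverable (no follow-up rows "
                "and no spacing tag)"
            )

    cov_names = [c for c in frame.columns if c not in _BASE_COLUMNS]
    n = len(subjects)
    diam = np.full((n, n_visits, N_POSITIONS), np.nan)
    covs = {c: np.full((n, n_visits), np.nan) for c in cov_names}
    pos_idx = {p: j for j, p in enumerate(POSITIONS)}
    si = frame["subject_id"].astype(str).map(sidx).to_numpy()
    ti = frame["visit_index"].to_numpy(dtype=int) - 1
    ji = frame["position"].map(pos_idx).to_numpy(dtype=int)
    diam[si, ti, ji] = frame["diameter_mm"].to_numpy(dtype=float)
    for c in cov_names:
        covs[c][si, ti] = frame[c].to_numpy(dtype=float)
    return CohortDataset(
        subject_ids=subjects,
        diam_mm=diam,
        covariates=covs,
        visit_spacing_years=spacing,
    )
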