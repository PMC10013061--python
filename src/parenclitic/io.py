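"""Cohort table reading, validation and writing.

A cohort table is a pandas ``DataFrame`` with one row per patient and columns

    patient_id, alb, bil, pt, cr, nh4, na, he, event, time, meld, child_pugh

Clinical columns are numeric with missing cells allowed (held as NaN and
never imputed); ``event`` is 1 for death or transplant within follow-up and 0
otherwise; ``time`` is follow-up time in days.  The on-disk format is plain
comma-separated UTF-8 with a header row and empty cells for missing values;
the HE column may contain the text grades (``unimpaired``/``minimal``/
``overt``) which are encoded to 0/1/2 on read.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import CohortParseError, CohortValidationError, SchemaError
from .variables import CLINICAL_VARIABLES, encode_he

#: Required columns in reading order.
COHORT_COLUMNS: tuple[str, ...] = (
    "patient_id",
    *CLINICAL_VARIABLES,
    "event",
    "time",
    "meld",
    "child_pugh",
)

_NUMERIC_COLUMNS = tuple(c for c in COHORT_COLUMNS if c != "patient_id")


def validate_cohort(df: pd.DataFrame) -> pd.DataFrame:
    """Validate and type a cohort table, returning a normalized copy.

    Checks column presence, patient-id uniqueness, numeric parsability,
    ``event`` in {0, 1}, positive ``time`` and HE grades in {0, 1, 2}.
    """
    missing_cols = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing_cols:
        raise SchemaError(f"cohort table is missing required columns: {missing_cols}")
    out = df.loc[:, list(COHORT_COLUMNS)].copy().reset_index(drop=True)

    ids = out["patient_id"].astype(str)
    if ids.isna().any() or (ids.str.len() == 0).any():
        raise CohortValidationError("patient_id must be non-empty")
    dupes = ids[ids.duplicated()].unique()
    if len(dupes):
        raise CohortValidationError(f"duplicate patient_id values: {list(dupes)}")
    out["patient_id"] = ids

    # HE accepts text grades; encode before the numeric pass.
    out["he"] = [
        np.nan if pd.isna(v) else float(encode_he(v)) for v in out["he"].tolist()
    ]

    for col in _NUMERIC_COLUMNS:
        if col == "he":
            continue
        parsed = pd.to_numeric(out[col], errors="coerce")
        bad = parsed.isna() & out[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise CohortParseError(
                f"non-numeric value {out[col].iloc[row]!r} in column {col!r} at row {row}"
            )
        out[col] = parsed.astype(float)

    event = out["event"]
    if event.isna().any() or not event.isin([0.0, 1.0]).all():
        raise CohortValidationError("event must be 0 or 1 for every patient")
    out["event"] = event.astype(int)

    time = out["time"]
    if time.isna().any() or (time <= 0).any():
        raise CohortValidationError("time must be positive for every patient")
    return out


def read_cohort(path: str) -> pd.DataFrame:
    """Read and validate a cohort CSV file."""
    df = pd.read_csv(path, dtype={"patient_id": str, "he": object})
    return validate_cohort(df)


def write_cohort(cohort: pd.DataFrame, path: str) -> None:
    """Write a cohort table as CSV (empty cells for missing values).

    ``write_cohort`` followed by :func:`read_cohort` reproduces the table
    exactly, missing cells included.
    """
    cohort.loc[:, list(COHORT_COLUMNS)].to_csv(path, index=False)


def apply_horizon(cohort: pd.DataFrame, horizon_days: float) -> pd.DataFrame:
    """Administrative censoring: events after the horizon become censored.

    Rows with ``time`` beyond the horizon are censored at the horizon
    (``event`` set to 0); all other rows are unchanged.
    """
    out = cohort.copy()
    late = out["time"] > horizon_days
    out.loc[late, "event"] = 0
    out.loc[late, "time"] = float(horizon_days)
    return out
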