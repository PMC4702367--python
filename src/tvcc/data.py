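"""Subject-level data model for case-control studies on a time axis.

The canonical in-memory container is a :class:`pandas.DataFrame` with one row
per subject and the columns

``id``
    opaque subject identifier (unique within a dataset);
``is_case``
    1 for cases, 0 for controls;
``entry_time``
    time from which the subject was at risk of being observed as a case
    (left-truncation entry, on the study time scale; 0 if none);
``index_time``
    event time for cases; last known event-free time (interview / censoring
    age) for controls;
``exposure``
    binary exposure indicator;
``exposure_time``
    time at which exposure began (0 = exposed from the time origin); NaN for
    never-exposed subjects;
``stratum``
    frequency-matching stratum label (birth cohort in the vaccine setting);
``z1 .. zK``
    optional covariate columns with time-constant effects.

Times are continuous (fractional years); ages are never rounded to integers,
so the half-open period-boundary semantics stay exact.
"""

from __future__ import annotations

import re

import pandas as pd

from .errors import DataError

__all__ = [
    "SUBJECT_COLUMNS",
    "covariate_columns",
    "validate_subjects",
    "read_subjects",
    "write_subjects",
]

#: Required columns of a subject table, in canonical order.
SUBJECT_COLUMNS = (
    "id",
    "is_case",
    "entry_time",
    "index_time",
    "exposure",
    "exposure_time",
    "stratum",
)

_COVARIATE_RE = re.compile(r"z\d+")


def covariate_columns(subjects: pd.DataFrame) -> list[str]:
    """Names of the covariate columns (``z1``, ``z2``, ...) in column order."""
    return [c for c in subjects.columns if _COVARIATE_RE.fullmatch(str(c))]


def validate_subjects(subjects: pd.DataFrame) -> pd.DataFrame:
    """Validate a subject table against the schema invariants.

    Returns the (possibly dtype-coerced) table; raises :class:`DataError`
    describing the first violated invariant otherwise.
    """
    missing = [c for c in SUBJECT_COLUMNS if c not in subjects.columns]
    if missing:
        raise DataError(f"subject table is missing required columns {missing}")
    df = subjects.copy()
    for col in ("entry_time", "index_time", "exposure_time"):
        df[col] = pd.to_numeric(df[col], errors="raise").astype(float)
    df["is_case"] = df["is_case"].astype(int)
    df["exposure"] = pd.to_numeric(df["exposure"], errors="raise")
    if not df["is_case"].isin((0, 1)).all():
        raise DataError("is_case must be 0 or 1")
    if df["id"].duplicated().any():
        dup = df.loc[df["id"].duplicated(), "id"].iloc[0]
        raise DataError(f"duplicate subject id {dup!r}")
    if (df["entry_time"] < 0).any():
        bad = df.loc[df["entry_time"] < 0, "id"].iloc[0]
        raise DataError(f"entry_time < 0 for subject {bad!r}")
    if (df["index_time"] <= df["entry_time"]).any():
        bad = df.loc[df["index_time"] <= df["entry_time"], "id"].iloc[0]
        raise DataError(f"index_time must exceed entry_time (subject {bad!r})")
    et = df["exposure_time"]
    if (et.dropna() < 0).any():
        raise DataError("exposure_time must be >= 0 where present")
    # exposed subjects without an explicit exposure time are exposed from the
    # time origin; never-exposed subjects carry NaN
    df.loc[(df["exposure"] != 0) & et.isna(), "exposure_time"] = 0.0
    zcols = covariate_columns(df)
    if zcols and df[zcols].isna().any().any():
        raise DataError("covariate columns must not contain missing values")
    return df


def read_subjects(path) -> pd.DataFrame:
    """Read a subject table from delimited text (CSV with header)."""
    df = pd.read_csv(path)
    return validate_subjects(df)


def write_subjects(subjects: pd.DataFrame, path) -> None:
    """Write a subject table as CSV (never-exposed subjects get an empty
    ``exposure_time`` field)."""
    cols = list(SUBJECT_COLUMNS) + covariate_columns(subjects)
    subjects.loc[:, cols].to_csv(path, index=False)
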