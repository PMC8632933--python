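"""Cohort table schema, validation and CSV round-trip.

The cohort is a plain :class:`pandas.DataFrame`, one row per subject, with
demographics, vascular risk factors, precomputed MRI marker summaries and
follow-up/vital status.  Booleans are stored as 0/1 integers, sex as the
strings ``male``/``female``; the optional continuous covariates (systolic
blood pressure, LDL cholesterol, HbA1c) may contain missing values.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd


class CohortValidationError(ValueError):
    """Raised when a cohort table violates the schema; messages cite row numbers."""


#: Column order of the cohort CSV.
COLUMNS = [
    "subject_id",
    "age_years",
    "sex",
    "hypertension",
    "diabetes",
    "dyslipidemia",
    "smoking",
    "sbp_mmhg",
    "ldl_mg_dl",
    "hba1c_pct",
    "wmh_volume_ml",
    "tiv_ml",
    "lacune_count",
    "cmb_lobar",
    "cmb_deep",
    "cmb_infratentorial",
    "followup_years",
    "died",
]

BOOL_COLUMNS = ["hypertension", "diabetes", "dyslipidemia", "smoking", "died"]
COUNT_COLUMNS = ["lacune_count", "cmb_lobar", "cmb_deep", "cmb_infratentorial"]
OPTIONAL_CONTINUOUS = ["sbp_mmhg", "ldl_mg_dl", "hba1c_pct"]

#: Phenotype output columns (mirrors the per-subject classification result).
RESULT_COLUMNS = [
    "subject_id",
    "wmh_ratio",
    "severe_wmh",
    "cmb_topography",
    "csvd_type",
    "csvd_score",
    "lacune_only_flag",
]

CSVD_TYPES = ["control", "type1", "type2", "type3", "type4"]


def _bad_rows(mask: pd.Series) -> str:
    rows = list(np.flatnonzero(np.asarray(mask))[:10])
    return ", ".join(str(r) for r in rows)


def validate_cohort(df: pd.DataFrame, require_unique_ids: bool = True) -> pd.DataFrame:
    """Validate and coerce a cohort table.

    Returns a copy with canonical dtypes.  Raises
    :class:`CohortValidationError` naming offending rows (0-based, excluding
    the header) on the first violated constraint.
    """
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise CohortValidationError(f"missing columns: {missing}")
    if len(df) == 0:
        raise CohortValidationError("empty cohort")

    out = df.loc[:, COLUMNS].reset_index(drop=True).copy()
    out["subject_id"] = out["subject_id"].astype(str)
    if require_unique_ids and out["subject_id"].duplicated().any():
        dupes = out.loc[out["subject_id"].duplicated(), "subject_id"].unique()[:5]
        raise CohortValidationError(f"duplicate subject_id values: {list(dupes)}")

    bad_sex = ~out["sex"].isin(["male", "female"])
    if bad_sex.any():
        raise CohortValidationError(f"sex must be male/female; rows {_bad_rows(bad_sex)}")

    for col in ["age_years", "wmh_volume_ml", "tiv_ml", "followup_years"] + OPTIONAL_CONTINUOUS:
        out[col] = pd.to_numeric(out[col], errors="coerce")
    for col in ["age_years", "wmh_volume_ml", "tiv_ml", "followup_years"]:
        if out[col].isna().any():
            raise CohortValidationError(
                f"{col} missing or non-numeric; rows {_bad_rows(out[col].isna())}"
            )

    for col in BOOL_COLUMNS:
        vals = pd.to_numeric(out[col], errors="coerce")
        bad = ~vals.isin([0, 1])
        if bad.any():
            raise CohortValidationError(f"{col} must be 0/1; rows {_bad_rows(bad)}")
        out[col] = vals.astype(int)

    for col in COUNT_COLUMNS:
        vals = pd.to_numeric(out[col], errors="coerce")
        bad = vals.isna() | (vals < 0) | (vals != np.floor(vals))
        if bad.any():
            raise CohortValidationError(
                f"{col} must be a non-negative integer; rows {_bad_rows(bad)}"
            )
        out[col] = vals.astype(int)

    checks = [
        ("age_years", out["age_years"] <= 0, "must be > 0"),
        ("tiv_ml", out["tiv_ml"] <= 0, "must be > 0"),
        ("wmh_volume_ml", out["wmh_volume_ml"] < 0, "must be >= 0"),
        ("wmh_volume_ml", out["wmh_volume_ml"] > out["tiv_ml"], "exceeds tiv_ml"),
        ("followup_years", out["followup_years"] <= 0, "must be > 0"),
    ]
    for col, bad, msg in checks:
        if bad.any():
            raise CohortValidationError(f"{col} {msg}; rows {_bad_rows(bad)}")
    return out


def load_cohort_csv(path: str | Path) -> pd.DataFrame:
    """Read and validate a cohort CSV."""
    df = pd.read_csv(path, dtype={"subject_id": str})
    try:
        return validate_cohort(df)
    except CohortValidationError as err:
        raise CohortValidationError(f"{path}: {err}") from None


def write_cohort_csv(df: pd.DataFrame, path: str | Path) -> None:
    """Write a cohort table in the canonical column order."""
    df.loc[:, COLUMNS].to_csv(path, index=False)
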