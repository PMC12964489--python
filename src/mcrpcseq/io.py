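"""Reading and writing the delimited-text claim tables.

Input schemas (header row, ISO-8601 dates, one record per row):

* diagnoses: patient_id, icd10, date
* prescriptions: patient_id, drug_id, date, days_supplied (may be blank)
* labs: patient_id, test, date, value
* patients: patient_id, birth_year, sex

Rows failing validation (unparseable dates, negative values) are either
dropped with a logged diagnostic or raise, per the configured policy.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

logger = logging.getLogger("mcrpcseq")

SCHEMAS: dict[str, list[str]] = {
    "diagnoses": ["patient_id", "icd10", "date"],
    "prescriptions": ["patient_id", "drug_id", "date", "days_supplied"],
    "labs": ["patient_id", "test", "date", "value"],
    "patients": ["patient_id", "birth_year", "sex"],
}

NUMERIC_COLUMNS = {"days_supplied", "value", "birth_year"}
OPTIONAL_NUMERIC = {"days_supplied"}


class SchemaError(ValueError):
    """A table does not conform to its declared schema."""


def read_table(path: str | Path, kind: str, *, on_bad_row: str = "drop") -> pd.DataFrame:
    """Read one input table, validating against its schema."""
    columns = SCHEMAS[kind]
    df = pd.read_csv(path, dtype={"patient_id": str})
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    df = df[columns].copy()
    bad = pd.Series(False, index=df.index)
    if "date" in columns:
        parsed = pd.to_datetime(df["date"], format="%Y-%m-%d", errors="coerce")
        bad |= parsed.isna()
        df["date"] = parsed
    for col in NUMERIC_COLUMNS & set(columns):
        values = pd.to_numeric(df[col], errors="coerce")
        if col in OPTIONAL_NUMERIC:
            bad |= values.notna() & (values <= 0)
        else:
            bad |= values.isna() | (values < 0)
        df[col] = values
    if bad.any():
        diagnostics = df[bad]
        for i, row in diagnostics.head(20).iterrows():
            logger.warning("%s row %d rejected: %s", kind, i, row.to_dict())
        if on_bad_row == "error":
            raise SchemaError(f"{path}: {int(bad.sum())} invalid rows")
        logger.warning("%s: dropped %d invalid rows", kind, int(bad.sum()))
        df = df[~bad]
    return df.reset_index(drop=True)


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path
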