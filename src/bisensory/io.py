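"""Validated delimited-table I/O for subject and trial data.

Subject table columns: subject_id, group {NT, ASD}, age_years, sex, piq,
viq, fsiq (plus optional fa_count). Trial table columns: subject_id, block,
trial_idx, condition {A, V, AV}, isi_ms, rt_ms (empty = miss), n_presses.
A loader shim maps common public-export column names onto this schema.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import CONDITIONS, GROUPS

SUBJECT_COLUMNS = ["subject_id", "group", "age_years", "sex", "piq", "viq",
                   "fsiq"]
TRIAL_COLUMNS = ["subject_id", "block", "trial_idx", "condition", "isi_ms",
                 "rt_ms", "n_presses"]

#: loose column-name shim for externally exported tables
COLUMN_SHIM = {
    "subject": "subject_id", "id": "subject_id", "sub": "subject_id",
    "diagnosis": "group", "dx": "group", "age": "age_years",
    "gender": "sex", "cond": "condition", "stim": "condition",
    "isi": "isi_ms", "rt": "rt_ms", "presses": "n_presses",
    "trial": "trial_idx",
}


class SchemaError(ValueError):
    pass


def _shim(df: pd.DataFrame) -> pd.DataFrame:
    return df.rename(columns={c: COLUMN_SHIM.get(c.lower(), c)
                              for c in df.columns})


def read_subject_table(path: str | Path) -> pd.DataFrame:
    df = _shim(pd.read_csv(path))
    missing = [c for c in SUBJECT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing subject columns {missing}")
    bad = ~df["group"].isin(GROUPS)
    if bad.any():
        row = df.index[bad][0]
        raise SchemaError(f"{path}: row {row}: unknown group "
                          f"{df.loc[row, 'group']!r} (column 'group')")
    if (df["age_years"] <= 0).any():
        raise SchemaError(f"{path}: non-positive age_years")
    return df


def read_trial_table(path: str | Path) -> pd.DataFrame:
    df = _shim(pd.read_csv(path))
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing trial columns {missing}")
    bad = ~df["condition"].isin(CONDITIONS)
    if bad.any():
        row = df.index[bad][0]
        raise SchemaError(f"{path}: row {row}: unknown condition "
                          f"{df.loc[row, 'condition']!r} (column 'condition')")
    for col in ("isi_ms", "rt_ms"):
        neg = df[col].notna() & (df[col] <= 0)
        if neg.any():
            row = df.index[neg][0]
            raise SchemaError(f"{path}: row {row}: non-positive {col} "
                              f"({df.loc[row, col]})")
    df["rt_ms"] = df["rt_ms"].astype(float)  # empty cells parse as NaN = miss
    return df


def write_subject_table(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def write_trial_table(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    cols = [c for c in TRIAL_COLUMNS if c in df.columns] \
        + [c for c in df.columns if c not in TRIAL_COLUMNS]
    df[cols].to_csv(path, index=False, float_format="%.6g")
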