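"""The project-standard trial table: one CSV row per trial.

Columns (stable order): subject, group, frame, session, block, trial,
tp_code, tot_code, P, a, A, choice, rt_ms, generating_process (optional).
choice is 1 (safe) / 0 (risky) or empty for unanswered stimulus rows; rt_ms
is in milliseconds.  Reading validates the schema and reports offending CSV
line numbers.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["COLUMNS", "SchemaError", "read_trials", "write_trials", "validate_trials"]

COLUMNS = [
    "subject", "group", "frame", "session", "block", "trial",
    "tp_code", "tot_code", "P", "a", "A", "choice", "rt_ms",
    "generating_process",
]

REQUIRED = COLUMNS[:13]  # generating_process is optional


class SchemaError(ValueError):
    pass


def _lines(mask: pd.Series) -> str:
    # CSV line numbers: +2 for the header line and 1-based indexing
    nums = (np.nonzero(mask.to_numpy())[0] + 2).tolist()
    shown = ", ".join(map(str, nums[:10]))
    return shown + (" ..." if len(nums) > 10 else "")


def validate_trials(df: pd.DataFrame) -> pd.DataFrame:
    """Schema validation; raises SchemaError citing CSV line numbers."""
    missing = [c for c in REQUIRED if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {missing}")
    if len(df) == 0:
        raise SchemaError("empty trial table")
    choice = pd.to_numeric(df["choice"], errors="coerce")
    bad = df["choice"].notna() & ~choice.isin([0, 1])
    if bad.any():
        raise SchemaError(
            f"choice must be 0, 1 or empty; bad value(s) on line(s) {_lines(bad)}"
        )
    rt = pd.to_numeric(df["rt_ms"], errors="coerce")
    bad = df["rt_ms"].notna() & ~(rt > 0)
    if bad.any():
        raise SchemaError(f"rt_ms must be > 0; bad value(s) on line(s) {_lines(bad)}")
    P = pd.to_numeric(df["P"], errors="coerce")
    bad = ~((P > 0) & (P < 1))
    if bad.any():
        raise SchemaError(f"P must lie in (0,1); bad value(s) on line(s) {_lines(bad)}")
    for col in ("tp_code", "tot_code"):
        v = pd.to_numeric(df[col], errors="coerce")
        bad = ~v.isin([-1, 0, 1])
        if bad.any():
            raise SchemaError(
                f"{col} must be -1, 0 or 1; bad value(s) on line(s) {_lines(bad)}"
            )
    return df


def read_trials(path) -> pd.DataFrame:
    """Read and validate a trial-table CSV."""
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as err:
        raise SchemaError(f"empty file: {path}") from err
    validate_trials(df)
    for col in ("block", "trial", "tp_code", "tot_code"):
        df[col] = df[col].astype(int)
    if df["choice"].notna().all():
        df["choice"] = df["choice"].astype(int)
    return df


def write_trials(df: pd.DataFrame, path) -> None:
    """Write the trial table with the stable column order."""
    cols = [c for c in COLUMNS if c in df.columns]
    df[cols].to_csv(path, index=False, float_format="%.12g")
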