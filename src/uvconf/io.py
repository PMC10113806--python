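"""Reading and writing trial tables and result tables.

Trial tables travel as BIDS-events-style TSV: one row per trial, ``n/a``
for missing values (missed trials carry no response or confidence).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["read_events", "write_events", "write_table"]

REQUIRED_COLUMNS = [
    "onset",
    "duration",
    "task",
    "stim_class",
    "orientation",
    "response",
    "correct",
    "confidence",
    "missed",
    "block",
    "run",
    "trial_in_block",
]

_DTYPES = {
    "onset": float,
    "duration": float,
    "orientation": float,
    "block": int,
    "run": int,
    "trial_in_block": int,
}


def read_events(path) -> pd.DataFrame:
    """Read and validate a BIDS-style events TSV into a trial table."""
    path = Path(path)
    table = pd.read_csv(path, sep="\t", na_values=["n/a"], comment="#")
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"{path.name} is missing required columns: {missing}")
    try:
        for col, typ in _DTYPES.items():
            table[col] = table[col].astype(typ)
        table["missed"] = table["missed"].astype(bool)
        table["confidence"] = table["confidence"].astype("Int64")
        table["correct"] = table["correct"].astype("boolean")
        for col in ("task", "stim_class", "response"):
            table[col] = table[col].where(table[col].notna(), pd.NA)
    except (TypeError, ValueError) as err:
        raise ValueError(f"{path.name} has ill-typed column: {err}") from err
    bad = (~table["missed"]) & table["confidence"].isna()
    if bad.any():
        raise ValueError(
            f"{path.name}: {int(bad.sum())} non-missed trials lack a confidence rating"
        )
    return table


def write_events(table: pd.DataFrame, path, header_comment: str | None = None) -> None:
    """Write a trial table as TSV with ``n/a`` for missing entries."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out = table.copy()
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        out.to_csv(fh, sep="\t", index=False, na_rep="n/a")


def write_table(df: pd.DataFrame, path, header_comment: str | None = None, index=False) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, sep="\t", index=index, na_rep="n/a", float_format="%.6g")
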