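"""Dataset I/O for the rectangular event-table dialect.

One row per dosing or observation event.  Columns (units): ID; TIME (h);
AMT (mg) and RATE (mg/h) on dose rows; EVID (1 dose, 0 observation); CMT
(1 plasma, 2 urine); DV (mg/L); BLQ (1 when below the quantitation limit);
LLOQ (mg/L); MDV; URINEVOL (ml, urine rows); covariates AGE (y), WTKG (kg),
HTCM (cm), SEX (0 male / 1 female), RACE (0 other / 1 black), SCR (mg/dl),
PHASE (1/3) and optionally EGFR / BSA (derived when absent).  A urine row
at TIME t covers the collection interval from the subject's previous urine
row (or time 0) to t.  Files are plain comma-separated text.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .estimation import DataError, PKData

__all__ = ["REQUIRED_COLUMNS", "KNOWN_COLUMNS", "read_dataset",
           "write_dataset", "run_record"]

REQUIRED_COLUMNS = ("ID", "TIME", "EVID", "CMT", "DV")
KNOWN_COLUMNS = (
    "ID", "TIME", "AMT", "RATE", "EVID", "CMT", "DV", "BLQ", "LLOQ", "MDV",
    "URINEVOL", "AGE", "WTKG", "HTCM", "SEX", "RACE", "SCR", "EGFR", "BSA",
    "BMI", "PHASE", "RENAL", "OUTLIER",
)


def read_dataset(path) -> pd.DataFrame:
    """Read and validate an event table from delimited text.

    Unknown columns trigger a warning; missing required columns, unsorted
    times within a subject, or malformed numeric fields raise
    :class:`DataError` naming the offending row.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = set(REQUIRED_COLUMNS) - set(df.columns)
    if missing:
        raise DataError(f"{path}: missing required columns {sorted(missing)}")
    unknown = set(df.columns) - set(KNOWN_COLUMNS)
    if unknown:
        warnings.warn(f"{path}: ignoring unknown columns {sorted(unknown)}",
                      stacklevel=2)
    for c in ("TIME", "EVID", "CMT"):
        vals = pd.to_numeric(df[c], errors="coerce")
        bad = vals.isna() & df[c].notna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # header + 1-based
            raise DataError(f"{path}: malformed {c} at line {line}")
        df[c] = vals
    if "BLQ" in df:
        conflict = (df["BLQ"] == 1) & df["DV"].notna()
        if conflict.any():
            warnings.warn(
                f"{path}: DV present on {int(conflict.sum())} BLQ rows; "
                "ignored (BLQ rows carry the limit, not a value)",
                stacklevel=2,
            )
            df.loc[conflict, "DV"] = np.nan
    # full structural validation (sorted times, dose/urine fields, covariates)
    PKData(df)
    # per-subject covariate completeness report
    for c in ("AGE", "WTKG", "HTCM", "SCR"):
        if c in df:
            miss = df.groupby("ID")[c].first().isna()
            if miss.any():
                warnings.warn(
                    f"{path}: covariate {c} missing for subjects "
                    f"{list(miss.index[miss])[:5]}...",
                    stacklevel=2,
                )
    return df


def write_dataset(df: pd.DataFrame, path) -> Path:
    """Write an event table as comma-separated text (lossless round-trip)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path


def run_record(config: dict, seed: int) -> dict:
    """Reproducibility stamp: seed plus a hash of the configuration."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return {
        "seed": int(seed),
        "config_hash": hashlib.sha256(blob).hexdigest()[:16],
        "config": config,
    }
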