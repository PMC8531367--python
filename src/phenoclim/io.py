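"""CSV schemas and validated readers/writers.

All tables travel as plain CSV with ISO-8601 dates. Readers validate the
required columns up front (error names the missing column) and report
unparseable dates with their line numbers.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

OBSERVATION_COLUMNS = [
    "record_id", "species", "latitude", "longitude", "site", "date",
    "flower_annotation", "whole_plant",
]
CLIMATE_COLUMNS = ["site", "latitude", "longitude", "date", "tmin", "tmax", "precip"]


class SchemaError(ValueError):
    """A required column is missing or a value cannot be parsed."""


def _check_columns(df: pd.DataFrame, required, path) -> None:
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")


def _parse_dates(df: pd.DataFrame, path) -> pd.DataFrame:
    parsed = pd.to_datetime(df["date"], format="%Y-%m-%d", errors="coerce")
    bad = parsed.isna() & df["date"].notna()
    if bad.any():
        line = int(bad.idxmax()) + 2  # +1 header, +1 1-based
        raise SchemaError(
            f"{path}: unparseable date {df.loc[bad.idxmax(), 'date']!r} at line {line}"
        )
    out = df.copy()
    out["date"] = parsed
    return out


def read_observations(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _check_columns(df, OBSERVATION_COLUMNS, path)
    return _parse_dates(df, path)


def read_climate(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _check_columns(df, CLIMATE_COLUMNS, path)
    return _parse_dates(df, path)


def write_table(df: pd.DataFrame, path) -> None:
    """Write any table with ISO dates; lossless round trip for typed columns."""
    out = df.copy()
    if "date" in out.columns:
        out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    out.to_csv(path, index=False)


def write_json(obj, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=str)


def read_json(path):
    with open(path) as fh:
        return json.load(fh)
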