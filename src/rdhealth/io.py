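"""Reading and writing survey tables and configuration files."""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd
import yaml

logger = logging.getLogger("rdhealth")

__all__ = ["read_survey_csv", "write_table", "load_config_file"]


def read_survey_csv(path, column_map: dict | None = None) -> pd.DataFrame:
    """Read respondent-level microdata from CSV.

    ``column_map`` maps canonical names (e.g. ``income_pc``) to the file's
    column names; mapped columns are renamed to canonical.  Rows with
    missing values in any mapped column are dropped (invalid records:
    nulls, refusals, don't-knows) and the count is logged and stored in
    ``df.attrs['n_dropped']``.
    """
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    if len(df) == 0:
        raise ValueError(f"{path}: no data rows")
    column_map = column_map or {}
    missing = [src for src in column_map.values() if src not in df.columns]
    if missing:
        raise KeyError(
            f"{path}: mapped column(s) {missing} not found; "
            f"available: {list(df.columns)}"
        )
    df = df.rename(columns={src: dst for dst, src in column_map.items()})
    check_cols = list(column_map) if column_map else list(df.columns)
    before = len(df)
    df = df.dropna(subset=check_cols).reset_index(drop=True)
    n_dropped = before - len(df)
    if n_dropped:
        logger.info("dropped %d row(s) with missing values in %s",
                    n_dropped, check_cols)
    if len(df) == 0:
        raise ValueError(f"{path}: all rows dropped as invalid")
    df.attrs["n_dropped"] = n_dropped
    return df


def write_table(df: pd.DataFrame, path, sep: str = ",") -> None:
    """Write a table to text (CSV/TSV) with full float precision."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep=sep, index=False, float_format="%.17g")


def load_config_file(path) -> dict:
    """Load a JSON or YAML configuration mapping."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a mapping at top level")
    return data
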