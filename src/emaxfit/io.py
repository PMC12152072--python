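"""CSV and config file handling for the command-line surface."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = ["read_dose_response", "write_dose_response", "load_config", "SCHEMA_VERSION"]

SCHEMA_VERSION = 1


def read_dose_response(path) -> np.ndarray:
    """Read a ``dose,response`` CSV (header required) into an (n, 2) array."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: file is empty") from None
    if list(df.columns[:2]) != ["dose", "response"]:
        raise ValueError(
            f"{path}: expected header 'dose,response', got {list(df.columns)!r}"
        )
    if len(df) == 0:
        raise ValueError(f"{path}: no data rows")
    for col in ("dose", "response"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.index[vals.isna() & df[col].notna()]
        if len(bad) or vals.isna().any():
            row = int((vals.isna()).idxmax()) + 2  # header is line 1
            raise ValueError(f"{path}: non-numeric or missing '{col}' at line {row}")
        df[col] = vals
    return df[["dose", "response"]].to_numpy(dtype=float)


def write_dose_response(path, records) -> None:
    recs = np.asarray(records, dtype=float)
    pd.DataFrame(recs, columns=["dose", "response"]).to_csv(path, index=False)


def load_config(path) -> dict:
    """Load a YAML or JSON configuration mapping."""
    path = Path(path)
    text = path.read_text()
    cfg = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg
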