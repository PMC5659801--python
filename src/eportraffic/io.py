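"""Readers, writers and reproducibility plumbing.

The canonical interchange format is a long CSV with columns
``cell_id, condition, observable, time_min, value_au`` (times in
minutes, values in arbitrary fluorescence units; no implicit unit
conversion on I/O).  XLSX workbooks in the same layout — or in wide
layout with one column per observable — are accepted read-only.

Result files are JSON with a provenance block (schema version, seed,
config hash, timestamp); fits, profiles and analyses round-trip through
:func:`write_results` / :func:`read_results`.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from .observation import OBSERVABLE_WEIGHTS

__all__ = [
    "read_trajectories",
    "write_trajectories",
    "write_results",
    "read_results",
    "config_hash",
    "SCHEMA_VERSION",
]

SCHEMA_VERSION = 1

TABLE_COLUMNS = ("cell_id", "condition", "observable", "time_min", "value_au")
_KNOWN_OBSERVABLES = set().union(*(set(w) for w in OBSERVABLE_WEIGHTS.values()))
_KNOWN_CONDITIONS = set(OBSERVABLE_WEIGHTS)


def read_trajectories(path: str | Path, dialect: str | None = None) -> pd.DataFrame:
    """Read and validate a trajectory table (long CSV or XLSX).

    Wide sheets (one column per observable) are melted to long format.
    Raises ``ValueError`` with row context for duplicate
    (cell, observable, time) keys, unknown observables or conditions,
    non-numeric values and negative times.
    """
    path = Path(path)
    if dialect is None:
        dialect = "xlsx" if path.suffix.lower() in (".xlsx", ".xls") else "csv"
    if dialect == "csv":
        df = pd.read_csv(path)
    elif dialect == "xlsx":
        df = pd.read_excel(path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    if "observable" not in df.columns:
        id_cols = [c for c in ("cell_id", "condition", "time_min") if c in df.columns]
        value_cols = [c for c in df.columns if c not in id_cols]
        df = df.melt(
            id_vars=id_cols, value_vars=value_cols,
            var_name="observable", value_name="value_au",
        ).dropna(subset=["value_au"])

    missing = set(TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    df = df.loc[:, list(TABLE_COLUMNS)].copy()

    bad = df[~df["condition"].isin(_KNOWN_CONDITIONS)]
    if not bad.empty:
        raise ValueError(
            f"unknown condition {bad['condition'].iloc[0]!r} at row {bad.index[0]}"
        )
    bad = df[~df["observable"].isin(_KNOWN_OBSERVABLES)]
    if not bad.empty:
        raise ValueError(
            f"unknown observable {bad['observable'].iloc[0]!r} at row {bad.index[0]}"
        )
    for col in ("time_min", "value_au"):
        values = pd.to_numeric(df[col], errors="coerce")
        bad_rows = df.index[values.isna()]
        if len(bad_rows):
            raise ValueError(
                f"non-numeric {col} {df.loc[bad_rows[0], col]!r} at row {bad_rows[0]}"
            )
        df[col] = values
    if not np.isfinite(df["value_au"]).all():
        row = df.index[~np.isfinite(df["value_au"])][0]
        raise ValueError(f"non-finite value at row {row}")
    if (df["time_min"] < 0).any():
        row = df.index[df["time_min"] < 0][0]
        raise ValueError(f"negative time at row {row}")
    dup = df.duplicated(subset=["cell_id", "observable", "time_min"], keep=False)
    if dup.any():
        first = df[dup].iloc[0]
        raise ValueError(
            "duplicate (cell, observable, time) key "
            f"({first['cell_id']}, {first['observable']}, {first['time_min']}) "
            f"at row {df.index[dup][0]}"
        )
    return df.reset_index(drop=True)


def write_trajectories(table: pd.DataFrame, path: str | Path) -> Path:
    """Write a long-format trajectory table to CSV."""
    path = Path(path)
    table.loc[:, list(TABLE_COLUMNS)].to_csv(path, index=False)
    return path


# ---------------------------------------------------------------------------
# JSON results with provenance


def config_hash(config: Mapping[str, Any] | None) -> str:
    payload = json.dumps(config or {}, sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.DataFrame):
        return {"__dataframe__": obj.to_dict(orient="split")}
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_results(
    obj: Any,
    path: str | Path,
    seed: int,
    config: Mapping[str, Any] | None = None,
) -> Path:
    """Write a result object as JSON with a provenance block."""
    if seed is None:
        raise ValueError("provenance requires a seed")
    if hasattr(obj, "to_dict"):
        obj = obj.to_dict()
    payload = {
        "schema_version": SCHEMA_VERSION,
        "seed": int(seed),
        "config": _jsonable(config or {}),
        "config_hash": config_hash(config),
        "created": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "result": _jsonable(obj),
    }
    path = Path(path)
    path.write_text(json.dumps(payload, indent=1))
    return path


def read_results(path: str | Path) -> dict:
    """Read a result file, validating its provenance block."""
    payload = json.loads(Path(path).read_text())
    for key in ("schema_version", "seed", "config_hash", "result"):
        if key not in payload:
            raise ValueError(f"result file missing provenance field {key!r}")
    if payload["schema_version"] > SCHEMA_VERSION:
        raise ValueError(
            f"result schema {payload['schema_version']} newer than supported {SCHEMA_VERSION}"
        )
    result = payload["result"]
    return payload | {"result": _undataframe(result)}


def _undataframe(obj: Any) -> Any:
    if isinstance(obj, dict):
        if set(obj) == {"__dataframe__"}:
            return pd.DataFrame(**obj["__dataframe__"])
        return {k: _undataframe(v) for k, v in obj.items()}
    if isinstance(obj, list):
        return [_undataframe(v) for v in obj]
    return obj
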