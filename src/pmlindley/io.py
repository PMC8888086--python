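"""Reading samples and writing reports.

Samples arrive as plain text (one value per line) or single-column CSV with
an optional header; reports leave as JSON (stable key order) or CSV.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["read_sample", "write_report"]


def read_sample(path, column=None) -> np.ndarray:
    """Read a positive univariate sample from a text or CSV file.

    A header row is auto-detected; ``column`` selects a CSV column by name
    or position.  Non-numeric or non-positive entries raise a ValueError
    that names the offending line.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    values = []
    start = 0
    for lineno, raw in enumerate(lines, start=1):
        stripped = raw.strip()
        if not stripped:
            continue
        fields = [f for f in stripped.replace(",", " ").split() if f]
        if column is not None and isinstance(column, str):
            # resolve a named column from the header row
            if lineno == 1:
                try:
                    column = fields.index(column)
                except ValueError:
                    raise ValueError(
                        f"{path}: column {column!r} not found in header {fields}"
                    ) from None
                start = 1
                continue
        field = fields[column if isinstance(column, int) else 0]
        try:
            v = float(field)
        except ValueError:
            if lineno == start + 1 and not values:
                # treat a single leading non-numeric row as a header
                continue
            raise ValueError(
                f"{path}, line {lineno}: non-numeric entry {field!r}"
            ) from None
        if not np.isfinite(v) or v <= 0.0:
            raise ValueError(
                f"{path}, line {lineno}: sample values must be positive and "
                f"finite, got {field!r}"
            )
        values.append(v)
    if not values:
        raise ValueError(f"{path}: no numeric values found")
    return np.asarray(values, dtype=float)


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        if hasattr(obj, "as_dict"):
            return _jsonable(obj.as_dict())
        return _jsonable(dataclasses.asdict(obj))
    if hasattr(obj, "as_dict"):
        return _jsonable(obj.as_dict())
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.DataFrame):
        return json.loads(obj.to_json(orient="index"))
    return obj


def write_report(report, path, format: str = "json") -> None:
    """Write a fit/comparison/simulation report deterministically.

    JSON output keeps insertion order (stable across runs for the same
    inputs); CSV expects a DataFrame-like report.
    """
    path = Path(path)
    if format == "json":
        path.write_text(json.dumps(_jsonable(report), indent=2) + "\n")
    elif format == "csv":
        if isinstance(report, pd.DataFrame):
            report.to_csv(path)
        elif hasattr(report, "table"):
            report.table.to_csv(path)
        elif hasattr(report, "to_dataframe"):
            report.to_dataframe().to_csv(path)
        else:
            pd.DataFrame(_jsonable(report)).to_csv(path)
    else:
        raise ValueError("format must be 'json' or 'csv'")
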