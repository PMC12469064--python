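"""CSV input, report output and config handling."""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Any, Optional, Union

import numpy as np
import pandas as pd

from .datatypes import Curve, Dataset, Report
from .errors import DomainError

__all__ = ["read_curves", "write_report", "read_report"]


def read_curves(path: Union[str, Path],
                kind: str = "growth",
                time_col: str = "time",
                response_col: str = "response",
                condition_col: str = "condition",
                condition_name: Optional[str] = None,
                response_units: str = "log CFU/g") -> Dataset:
    """Read a curves CSV into a Dataset.

    The file needs a header with time, response and condition columns
    (names configurable).  Rows are validated (numeric cells, no duplicate
    (condition, time) pairs) and sorted by condition then time; parse
    errors name the offending row (1-based, counting the header as row 1).
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in (time_col, response_col, condition_col) if c not in df.columns]
    if missing:
        raise DomainError(f"{path.name}: missing required column(s) {missing}; "
                          f"found {list(df.columns)}")
    for col in (time_col, response_col, condition_col):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad):
            row = int(bad[0]) + 2  # +1 header, +1 one-based
            raise DomainError(
                f"{path.name}: non-numeric value {df[col].iloc[bad[0]]!r} "
                f"in column {col!r} at row {row}")
        if coerced.isna().any():
            row = int(df.index[coerced.isna()][0]) + 2
            raise DomainError(f"{path.name}: empty cell in column {col!r} at row {row}")
        df[col] = coerced
    dup = df.duplicated(subset=[condition_col, time_col])
    if dup.any():
        row = int(df.index[dup][0]) + 2
        raise DomainError(
            f"{path.name}: duplicate (condition, time) pair at row {row}")
    df = df.sort_values([condition_col, time_col], kind="stable")

    default_name = "temperature" if kind == "growth" else "chlorine"
    name = condition_name or default_name
    curves = []
    for cond, grp in df.groupby(condition_col, sort=True):
        curves.append(Curve(
            times=grp[time_col].to_numpy(dtype=float),
            values=grp[response_col].to_numpy(dtype=float),
            condition=float(cond),
            condition_name=name,
            response_units=response_units,
        ))
    return Dataset(curves=curves, kind=kind)


def write_report(report: Report, path: Union[str, Path], fmt: str = "json") -> Path:
    """Serialise a Report to JSON (lossless) or a flat CSV parameter table.

    JSON uses Python's shortest round-trip float repr, so numeric fields
    keep full double precision.
    """
    path = Path(path)
    d = report.to_dict()
    if fmt == "json":
        path.write_text(json.dumps(d, indent=2, sort_keys=True) + "\n")
    elif fmt == "csv":
        rows = _flatten("", d)
        with path.open("w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["key", "value"])
            w.writerows(rows)
    else:
        raise DomainError(f"unknown report format {fmt!r}; use 'json' or 'csv'")
    return path


def read_report(path: Union[str, Path]) -> Report:
    """Read back a JSON report written by :func:`write_report`."""
    d = json.loads(Path(path).read_text())
    return Report.from_dict(d)


def _flatten(prefix: str, obj: Any):
    if isinstance(obj, dict):
        for k, v in sorted(obj.items()):
            yield from _flatten(f"{prefix}.{k}" if prefix else str(k), v)
    elif isinstance(obj, (list, tuple)):
        for i, v in enumerate(obj):
            yield from _flatten(f"{prefix}[{i}]", v)
    else:
        yield (prefix, "" if obj is None else repr(obj) if isinstance(obj, float) else obj)
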