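"""Reading and writing prevalence data and run configuration.

The prevalence format is a tidy, comma-separated, UTF-8 file with a
mandatory header ``replicate,time,class,count,n_assayed``.  Generation
metadata (model tag, population size, initial conditions, seed) travels in
``# key: json-value`` comment lines above the header, so a write/read round
trip is lossless in a single file.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from .observe import PrevalenceSeries

__all__ = ["read_prevalence_csv", "write_prevalence_csv", "load_config"]

_COLUMNS = ["replicate", "time", "class", "count", "n_assayed"]


def write_prevalence_csv(series: PrevalenceSeries, path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        for key, value in series.metadata.items():
            fh.write(f"# {key}: {json.dumps(value)}\n")
        series.data.to_csv(fh, index=False, lineterminator="\n")


def read_prevalence_csv(path) -> PrevalenceSeries:
    """Load and validate a prevalence CSV.

    Raises ``ValueError`` naming the offending line for malformed rows and
    for records with ``count > n_assayed``; an empty data section (header
    only) is a valid, empty series.
    """
    path = Path(path)
    metadata: dict[str, Any] = {}
    header_line = 0
    with path.open("r", encoding="utf-8") as fh:
        lines = fh.readlines()
    for i, line in enumerate(lines):
        if line.startswith("#"):
            key, _, raw = line[1:].partition(":")
            try:
                metadata[key.strip()] = json.loads(raw.strip())
            except json.JSONDecodeError:
                metadata[key.strip()] = raw.strip()
        else:
            header_line = i
            break
    else:  # all comments, or empty file
        raise ValueError(f"{path}: missing header line '{','.join(_COLUMNS)}'")

    header = [c.strip() for c in lines[header_line].strip().split(",")]
    if header != _COLUMNS:
        raise ValueError(
            f"{path}:{header_line + 1}: header must be '{','.join(_COLUMNS)}', got {header}")

    records = []
    for i, line in enumerate(lines[header_line + 1:], start=header_line + 2):
        if not line.strip():
            continue
        cells = line.rstrip("\n").split(",")
        if len(cells) != 5:
            raise ValueError(f"{path}:{i}: expected 5 fields, got {len(cells)}")
        try:
            records.append((cells[0], float(cells[1]), cells[2], int(cells[3]), int(cells[4])))
        except ValueError as exc:
            raise ValueError(f"{path}:{i}: malformed row ({exc})") from None
        if records[-1][3] < 0 or records[-1][3] > records[-1][4]:
            raise ValueError(f"{path}:{i}: count {records[-1][3]} outside "
                             f"[0, n_assayed={records[-1][4]}]")
    df = pd.DataFrame(records, columns=_COLUMNS)
    # replicate ids written as integers come back as integers
    if len(df):
        as_int = pd.to_numeric(df["replicate"], errors="coerce")
        if as_int.notna().all() and (as_int == as_int.astype(int)).all():
            df["replicate"] = as_int.astype(int)
    series = PrevalenceSeries(df)
    series.metadata = metadata
    return series


def load_config(path) -> dict[str, Any]:
    """Load a YAML (or JSON — a YAML subset) run-configuration mapping."""
    with Path(path).open("r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if cfg is None:
        return {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: configuration must be a mapping")
    return cfg
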