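"""Event-table file format: CSV with '#'-prefixed metadata lines.

One row per scanned droplet.  Required columns: droplet_id, green_peak,
red_peak, red_width; optional: time_min, group_label, coalesced.  Floats are
serialized at 12 significant digits so a write -> read roundtrip is lossless
for practical purposes.
"""

from __future__ import annotations

import io as _stdio
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["SCHEMA_VERSION", "REQUIRED_COLUMNS", "SchemaError",
           "read_events", "write_events"]

SCHEMA_VERSION = "1"
REQUIRED_COLUMNS = ("droplet_id", "green_peak", "red_peak", "red_width")
OPTIONAL_COLUMNS = ("time_min", "group_label", "coalesced")


class SchemaError(ValueError):
    """Event table does not conform to the expected schema."""


def write_events(table: pd.DataFrame, path, metadata: dict | None = None) -> None:
    """Write an event table as commented-header CSV."""
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"event table is missing required column(s): {missing}")
    path = Path(path)
    buf = _stdio.StringIO()
    buf.write(f"# dropphage-events schema_version={SCHEMA_VERSION}\n")
    for key, value in (metadata or {}).items():
        buf.write(f"# {key}={value}\n")
    cols = [c for c in (*REQUIRED_COLUMNS, *OPTIONAL_COLUMNS) if c in table.columns]
    table[cols].to_csv(buf, index=False, float_format="%.12g")
    path.write_text(buf.getvalue())


def read_events(path) -> pd.DataFrame:
    """Read an event table, validating schema and cell types."""
    path = Path(path)
    try:
        table = pd.read_csv(path, comment="#")
    except pd.errors.ParserError as exc:
        raise SchemaError(f"could not parse {path}: {exc}") from exc
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(
            f"{path} is missing required column(s): {', '.join(missing)}"
        )
    for col in REQUIRED_COLUMNS + tuple(c for c in ("time_min",) if c in table.columns):
        if len(table) and not np.issubdtype(table[col].dtype, np.number):
            bad = table[~table[col].apply(_is_number)].index
            line = int(bad[0]) + 2 if len(bad) else "?"
            raise SchemaError(
                f"{path}: non-numeric value in column {col!r} near data line {line}"
            )
    if len(table):
        numeric = table[list(REQUIRED_COLUMNS)].to_numpy(dtype=float)
        if not np.all(np.isfinite(numeric)):
            raise SchemaError(f"{path}: non-finite values in required columns")
    return table


def _is_number(x) -> bool:
    try:
        float(x)
        return True
    except (TypeError, ValueError):
        return False
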