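"""Cohort-table CSV reading and writing with schema validation.

The cohort CSV stores only integer counts, never proportions, so every
downstream statistic can be recomputed exactly.  Required columns:
``mouse_id, tissue, pulse_week, pulse_day, analysis_day, n_cells, n_tagged``.
Optional columns: ``subset`` (transcription-factor stratum, default "all"),
``divided_recent`` (recent-division-marker-positive cells among ``n_cells``)
and per-marker count quadruples
``<marker>_tag_pos, <marker>_tag_tot, <marker>_untag_pos, <marker>_untag_tot``.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ValidationError

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = [
    "mouse_id",
    "tissue",
    "pulse_week",
    "pulse_day",
    "analysis_day",
    "n_cells",
    "n_tagged",
]
INTEGER_COLUMNS = ["pulse_week", "pulse_day", "analysis_day", "n_cells", "n_tagged"]


def _check_integer(table: pd.DataFrame, column: str) -> pd.Series:
    values = pd.to_numeric(table[column], errors="coerce")
    bad = values.isna() | (values != values.round())
    if bad.any():
        row = int(table.index[bad][0]) + 2  # header is line 1
        raise ValidationError(
            f"column {column!r} must contain integers; first violation at line {row}"
        )
    return values.astype(int)


def validate_cohort(table: pd.DataFrame, *, pulse_weeks: list[int] | None = None) -> pd.DataFrame:
    """Validate (and coerce) a cohort table in place; returns the table.

    Errors name the first offending row (1-based CSV line, counting the
    header) and column.
    """
    if table.empty:
        raise ValidationError("no records in cohort table")
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValidationError(f"cohort table is missing required columns {missing}")
    table = table.reset_index(drop=True)
    for column in INTEGER_COLUMNS:
        table[column] = _check_integer(table, column)
    for column in ("n_cells", "n_tagged"):
        neg = table[column] < 0
        if neg.any():
            row = int(table.index[neg][0]) + 2
            raise ValidationError(f"column {column!r} negative at line {row}")
    over = table["n_tagged"] > table["n_cells"]
    if over.any():
        row = int(table.index[over][0]) + 2
        raise ValidationError(f"n_tagged > n_cells at line {row}")
    if "subset" not in table.columns:
        table["subset"] = "all"
    table["subset"] = table["subset"].fillna("all")

    key = ["mouse_id", "tissue", "subset"]
    duplicated = table.duplicated(subset=key)
    if duplicated.any():
        row = int(table.index[duplicated][0]) + 2
        raise ValidationError(
            f"duplicate (mouse_id, tissue, subset) record at line {row}"
        )
    if pulse_weeks is not None:
        unknown = ~table["pulse_week"].isin(pulse_weeks)
        if unknown.any():
            row = int(table.index[unknown][0]) + 2
            raise ValidationError(
                f"pulse_week outside the declared design {sorted(pulse_weeks)} at line {row}"
            )
    # marker count quadruples: positives cannot exceed totals
    for col in table.columns:
        if col.endswith("_tag_pos") or col.endswith("_untag_pos"):
            tot_col = col.replace("_pos", "_tot")
            if tot_col in table.columns:
                bad = table[col].fillna(0) > table[tot_col].fillna(0)
                if bad.any():
                    row = int(table.index[bad][0]) + 2
                    raise ValidationError(
                        f"{col} exceeds {tot_col} at line {row}"
                    )
    return table


def read_cohort(path: str | Path, *, pulse_weeks: list[int] | None = None) -> pd.DataFrame:
    """Read and validate a cohort CSV.

    Raises :class:`ValidationError` naming the offending row/column when the
    schema is violated.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"cohort file not found: {path}")
    try:
        table = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ValidationError("no records in cohort table") from None
    return validate_cohort(table, pulse_weeks=pulse_weeks)


def write_cohort(table: pd.DataFrame, path: str | Path) -> None:
    """Write a cohort table as CSV (counts only, stable column order)."""
    table = validate_cohort(table.copy())
    optional = [c for c in table.columns if c not in REQUIRED_COLUMNS + ["subset"]]
    ordered = REQUIRED_COLUMNS + ["subset"] + sorted(optional)
    out = table[ordered].copy()
    for col in optional:
        if out[col].notna().all() and np.allclose(out[col], out[col].round()):
            out[col] = out[col].astype(int)
    out.to_csv(path, index=False)
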