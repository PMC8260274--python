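"""CSV schemas and schema-checked readers/writers.

All tables move as plain comma-separated files with documented headers.
Readers validate required columns and dtypes up front and raise
:class:`~spinedyn.errors.SchemaError` naming the file, row and column, so a
malformed input fails loudly at the boundary instead of deep in the
pipeline.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .errors import SchemaError
from .synthetic import (ANNOTATION_COLUMNS, DENSITOMETRY_COLUMNS,
                        ROTAROD_COLUMNS, TIMEPOINTS)

_NUMERIC = {
    "segment_length_um", "position_um", "protrusion_length_um",
    "head_neck_ratio", "latency_s", "day", "trial",
    "pERK_42", "pERK_44", "totalERK_42", "totalERK_44", "actin",
}
_BOOL = {"lateral", "occluded", "trained"}


def _check_columns(df: pd.DataFrame, required: list[str], path) -> None:
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"missing required column {col!r}",
                              file=str(path), column=col)


def _check_values(df: pd.DataFrame, columns: list[str], path) -> pd.DataFrame:
    for col in columns:
        if col in _NUMERIC:
            converted = pd.to_numeric(df[col], errors="coerce")
            bad = converted.isna() & df[col].notna()
            if bad.any():
                row = int(df.index[bad][0]) + 2  # 1-based + header line
                raise SchemaError(f"non-numeric value in column {col!r}",
                                  file=str(path), row=row, column=col)
            df[col] = converted
        if col in _BOOL and df[col].dtype == object:
            df[col] = df[col].astype(str).str.lower().map(
                {"true": True, "false": False, "1": True, "0": False})
            if df[col].isna().any():
                row = int(df.index[df[col].isna()][0]) + 2
                raise SchemaError(f"non-boolean value in column {col!r}",
                                  file=str(path), row=row, column=col)
    return df


def read_annotations(path: str | Path) -> pd.DataFrame:
    """Read a spine-annotation table, validating schema and timepoints."""
    df = pd.read_csv(path)
    _check_columns(df, ANNOTATION_COLUMNS, path)
    df = _check_values(df, ANNOTATION_COLUMNS, path)
    bad_tp = ~df["timepoint"].isin(TIMEPOINTS)
    if bad_tp.any():
        row = int(df.index[bad_tp][0]) + 2
        raise SchemaError(
            f"timepoint must be one of {TIMEPOINTS}",
            file=str(path), row=row, column="timepoint")
    return df


def read_rotarod(path: str | Path) -> pd.DataFrame:
    """Read a rotarod trial table, validating schema and latency range."""
    df = pd.read_csv(path)
    _check_columns(df, ROTAROD_COLUMNS, path)
    df = _check_values(df, ROTAROD_COLUMNS, path)
    bad = (df["latency_s"] < 0) | (df["latency_s"] > 180.0)
    if bad.any():
        row = int(df.index[bad][0]) + 2
        raise SchemaError("latency_s outside [0, 180]",
                          file=str(path), row=row, column="latency_s")
    dup = df.duplicated(["animal_id", "day", "trial"])
    if dup.any():
        row = int(df.index[dup][0]) + 2
        raise SchemaError("duplicate (animal_id, day, trial)",
                          file=str(path), row=row, column="trial")
    return df


def read_densitometry(path: str | Path) -> pd.DataFrame:
    """Read a densitometry table, validating schema and non-negative bands."""
    df = pd.read_csv(path)
    _check_columns(df, DENSITOMETRY_COLUMNS, path)
    df = _check_values(df, DENSITOMETRY_COLUMNS, path)
    for col in ("pERK_42", "pERK_44", "totalERK_42", "totalERK_44", "actin"):
        bad = df[col] < 0
        if bad.any():
            row = int(df.index[bad][0]) + 2
            raise SchemaError(f"negative band density in {col!r}",
                              file=str(path), row=row, column=col)
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a table as CSV without the index, creating parent dirs."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
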