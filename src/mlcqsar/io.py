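"""Reading and writing compound tables and model reports.

The package ships two fixture tables for the 65 heterocyclic drug-like
compounds of the study:

``table_2.csv``
    Per-compound parameters of the Foley retention fit: intercept
    ``inv_km`` (1/k_m), slope ``kam_over_km`` (K_AM/k_m, L mol^-1) and the
    coefficient of determination of the straight-line fit.

``table_3.csv``
    The descriptor/response matrix: micellar lipophilicity
    ``log_km_over_kam``, the blood-brain distribution endpoints ``log_bb``
    and ``log_bb_star``, and the in-silico descriptors TPSA, HBD, HBA,
    NRB, MW, polarizability ``alpha`` and parachor ``parachor_P``.

Both fixtures keep the Unicode minus sign (U+2212) of the source tables;
all loaders normalise it to ASCII ``-`` before numeric parsing.
"""

from __future__ import annotations

import logging
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ParseError, SchemaError, ValidationError

__all__ = [
    "DESCRIPTOR_COLUMNS",
    "RESPONSE_COLUMNS",
    "COLUMN_UNITS",
    "load_descriptor_table",
    "load_foley_table",
    "load_table2",
    "load_table3",
    "write_model_report",
    "format_model_report",
]

logger = logging.getLogger(__name__)

#: Columns of the descriptor table playing the role of model predictors.
DESCRIPTOR_COLUMNS = (
    "log_km_over_kam",
    "tpsa",
    "hbd",
    "hba",
    "nrb",
    "mw",
    "alpha",
    "parachor_P",
)

#: Columns playing the role of modelled responses.
RESPONSE_COLUMNS = ("log_bb", "log_bb_star")

#: Physical units of the numeric columns (dimensionless where omitted).
COLUMN_UNITS = {
    "tpsa": "A^2",
    "mw": "g mol^-1",
    "alpha": "A^3",
    "parachor_P": "m^3 mol^-1",
    "kam_over_km": "L mol^-1",
}

_INTEGER_COLUMNS = ("hbd", "hba", "nrb")

_UNICODE_MINUS = "−"


def _normalise_minus(frame: pd.DataFrame) -> pd.DataFrame:
    """Replace the Unicode minus with ASCII ``-`` in all object columns."""
    for col in frame.columns:
        if frame[col].dtype == object:
            # .str accessor keeps missing cells as NaN
            frame[col] = frame[col].str.replace(_UNICODE_MINUS, "-", regex=False).str.strip()
    return frame


def _parse_numeric(frame: pd.DataFrame, columns: Iterable[str]) -> pd.DataFrame:
    for col in columns:
        parsed = pd.to_numeric(frame[col], errors="coerce")
        bad = parsed.isna() & frame[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ParseError(
                f"non-numeric value {frame[col].iloc[row]!r} in column {col!r}, data row {row + 1}"
            )
        if parsed.isna().any():
            row = int(np.flatnonzero(parsed.isna().to_numpy())[0])
            raise ParseError(f"missing value in numeric column {col!r}, data row {row + 1}")
        frame[col] = parsed
    return frame


def load_descriptor_table(
    path: str | Path,
    schema: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Load a compound descriptor/response table from delimited text.

    Parameters
    ----------
    path : str or Path
        Comma-delimited UTF-8 file with a header row. A ``compound_id``
        column is required; the Unicode minus sign is accepted as a
        negative sign in numeric cells.
    schema : sequence of str, optional
        Names of numeric columns that must be present. Defaults to every
        non-identity column found in the file.

    Returns
    -------
    pandas.DataFrame
        One row per compound, numeric columns parsed to float (count
        descriptors HBD/HBA/NRB to integer), indexed 0..n-1 with
        ``compound_id`` as a regular column.

    Raises
    ------
    SchemaError
        If the file is empty or a required column is missing.
    ParseError
        If a numeric cell cannot be parsed.
    ValidationError
        On duplicate compound identifiers, non-finite values, or negative
        counts in HBD/HBA/NRB.
    """
    path = Path(path)
    try:
        raw = pd.read_csv(path, dtype=object, comment="#")
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{path}: file is empty") from exc
    if raw.empty:
        raise SchemaError(f"{path}: no data rows")
    if "compound_id" not in raw.columns:
        raise SchemaError(f"{path}: required column 'compound_id' is missing")

    required = list(schema) if schema is not None else [
        c for c in raw.columns if c not in ("compound_id", "class_label")
    ]
    missing = [c for c in required if c not in raw.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {', '.join(missing)}")

    frame = _normalise_minus(raw.copy())
    frame = _parse_numeric(frame, required)

    ids = frame["compound_id"]
    if ids.duplicated().any():
        dup = ids[ids.duplicated()].iloc[0]
        raise ValidationError(f"duplicate compound_id {dup!r}")

    values = frame[required].to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise ValidationError("non-finite descriptor value encountered")

    for col in _INTEGER_COLUMNS:
        if col in frame.columns:
            vals = frame[col].to_numpy(dtype=float)
            if (vals < 0).any() or not np.allclose(vals, np.round(vals)):
                raise ValidationError(f"column {col!r} must hold non-negative integers")
            frame[col] = frame[col].astype(int)

    frame.attrs["units"] = {c: COLUMN_UNITS.get(c, "") for c in frame.columns}
    return frame.reset_index(drop=True)


def load_foley_table(path: str | Path) -> pd.DataFrame:
    """Load a per-compound Foley parameter table.

    Expects columns ``compound_id``, ``inv_km`` (intercept 1/k_m),
    ``kam_over_km`` (slope K_AM/k_m) and ``r2``. Rows with missing values
    are skipped with a logged warning; an ``r2`` outside [0, 1] is a hard
    validation error.
    """
    path = Path(path)
    try:
        raw = pd.read_csv(path, dtype=object, comment="#")
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{path}: file is empty") from exc
    expected = ["compound_id", "inv_km", "kam_over_km", "r2"]
    missing = [c for c in expected if c not in raw.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {', '.join(missing)}")

    frame = _normalise_minus(raw[expected].copy())
    incomplete = frame[expected].isna().any(axis=1)
    if incomplete.any():
        for cid in frame.loc[incomplete, "compound_id"]:
            logger.warning("skipping incomplete Foley row for compound %s", cid)
        frame = frame[~incomplete]
    frame = _parse_numeric(frame, expected[1:])

    r2 = frame["r2"].to_numpy(dtype=float)
    if ((r2 < 0) | (r2 > 1)).any():
        bad = frame.loc[(frame["r2"] < 0) | (frame["r2"] > 1), "compound_id"].iloc[0]
        raise ValidationError(f"r2 outside [0, 1] for compound {bad!r}")
    if not np.isfinite(frame[expected[1:]].to_numpy(dtype=float)).all():
        raise ValidationError("non-finite Foley parameter encountered")
    return frame.reset_index(drop=True)


def _fixture_path(name: str) -> Path:
    return Path(str(resources.files("mlcqsar").joinpath("data", name)))


def load_table2() -> pd.DataFrame:
    """Return the packaged 65-compound Foley parameter fixture."""
    return load_foley_table(_fixture_path("table_2.csv"))


def load_table3() -> pd.DataFrame:
    """Return the packaged 65-compound descriptor/response fixture."""
    return load_descriptor_table(_fixture_path("table_3.csv"))


_REPORT_COLUMNS = [
    "label",
    "response",
    "predictors",
    "r2",
    "r2_adj",
    "r2_pred",
    "press",
    "max_vif",
    "ss",
    "mse",
    "fvalue",
    "p_value",
    "q2_loo",
    "press_loo",
]

_R_STATS = ("r2", "r2_adj", "r2_pred", "q2_loo")


def _stats_frame(stats) -> pd.DataFrame:
    rows = []
    for s in stats:
        d = s.to_dict() if hasattr(s, "to_dict") else dict(s)
        rows.append({c: d.get(c) for c in _REPORT_COLUMNS})
    return pd.DataFrame(rows, columns=_REPORT_COLUMNS)


def write_model_report(stats, path: str | Path) -> None:
    """Write a validation-statistics report (one row per model) as CSV.

    R-type statistics are written with fixed 4-decimal formatting so that
    a write/load round trip preserves them at reported precision.
    """
    stats = list(stats)
    if not stats:
        raise ValidationError("cannot write an empty model report")
    frame = _stats_frame(stats)
    for col in _R_STATS:
        frame[col] = frame[col].map(lambda v: f"{v:.4f}" if pd.notna(v) else "")
    for col in ("press", "ss", "mse", "press_loo"):
        frame[col] = frame[col].map(lambda v: f"{v:.4f}" if pd.notna(v) else "")
    frame["max_vif"] = frame["max_vif"].map(
        lambda v: f"{v:.1f}" if pd.notna(v) and np.isfinite(v) else "inf"
    )
    frame["fvalue"] = frame["fvalue"].map(
        lambda v: f"{v:.1f}" if pd.notna(v) and np.isfinite(v) else "inf"
    )
    frame["p_value"] = frame["p_value"].map(lambda v: f"{v:.5f}" if pd.notna(v) else "")
    frame.to_csv(path, index=False)


def format_model_report(stats) -> str:
    """Render the model report as a fixed-width human-readable table."""
    stats = list(stats)
    if not stats:
        raise ValidationError("cannot format an empty model report")
    frame = _stats_frame(stats)
    frame["predictors"] = frame["predictors"].map(
        lambda p: "+".join(p) if isinstance(p, (list, tuple)) else str(p)
    )
    with pd.option_context("display.float_format", lambda v: f"{v:.4f}", "display.width", 200):
        return frame.to_string(index=False)
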