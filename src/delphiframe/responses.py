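"""Panel response tables: panellist x criterion ordinal ratings.

A response table is a pandas DataFrame indexed by panellist id with one
column per criterion id.  Cells hold floats in {1..5} or NaN for a
"Do not know" reply.  The 5-point scale is Very low (1), Low (2),
Middle (3), High (4), Very high (5).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .codebook import CriterionHierarchy
from .errors import ValidationError

SCALE_LABELS = {1: "Very low", 2: "Low", 3: "Middle", 4: "High", 5: "Very high"}
DEFAULT_MISSING_TOKEN = "DNK"


def validate_responses(
    table: pd.DataFrame, codebook: CriterionHierarchy | None = None
) -> pd.DataFrame:
    """Validate a response table; returns the table with float cells.

    Rejects (never coerces) any non-missing cell outside {1..5} and any
    column the codebook does not know.
    """
    violations = []
    if codebook is not None:
        unknown = [c for c in table.columns if c not in codebook]
        for c in unknown:
            violations.append(f"unknown criterion column {c!r}")
    values = table.to_numpy(dtype=float, copy=True)
    bad = ~np.isnan(values) & (
        (values < 1) | (values > 5) | (values != np.round(values))
    )
    for r, c in zip(*np.nonzero(bad)):
        violations.append(
            f"row {table.index[r]!r}, criterion {table.columns[c]!r}: "
            f"value {table.iat[r, c]!r} not in 1..5"
        )
    if violations:
        raise ValidationError(violations)
    out = table.astype(float)
    out.columns = [str(c) for c in table.columns]
    return out


def read_responses(
    path: str | Path,
    codebook: CriterionHierarchy | None = None,
    missing_token: str = DEFAULT_MISSING_TOKEN,
) -> pd.DataFrame:
    """Read a panellist x criterion CSV with the declared missing token.

    The first column holds panellist ids; the header row holds criterion
    ids.  Any cell that is neither an integer 1-5 nor the missing token is
    a parse error carrying its row and criterion location.
    """
    raw = pd.read_csv(path, index_col=0, dtype=str, keep_default_na=False)
    violations = []
    parsed = pd.DataFrame(index=raw.index.astype(str), dtype=float)
    parsed.index.name = raw.index.name or "panellist"
    for col in raw.columns:
        cells = []
        for rid, cell in raw[col].items():
            cell = cell.strip()
            if cell == missing_token or cell == "":
                cells.append(np.nan)
                continue
            try:
                value = int(cell)
            except ValueError:
                violations.append(
                    f"row {rid!r}, criterion {col!r}: unparseable cell {cell!r}"
                )
                cells.append(np.nan)
                continue
            if not 1 <= value <= 5:
                violations.append(
                    f"row {rid!r}, criterion {col!r}: value {value} not in 1..5"
                )
            cells.append(float(value))
        parsed[str(col)] = cells
    if violations:
        raise ValidationError(violations)
    return validate_responses(parsed, codebook)


def write_responses(
    table: pd.DataFrame,
    path: str | Path,
    missing_token: str = DEFAULT_MISSING_TOKEN,
) -> None:
    """Write a response table as CSV (comma, UTF-8, DNK for missing)."""
    out = table.copy()
    out = out.map(lambda v: missing_token if pd.isna(v) else str(int(v)))
    out.index.name = table.index.name or "panellist"
    out.to_csv(path, encoding="utf-8")


def respondent_counts(table: pd.DataFrame) -> pd.Series:
    """Non-missing reply count per criterion."""
    return table.notna().sum(axis=0).astype(int)
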