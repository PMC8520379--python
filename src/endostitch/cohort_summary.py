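"""Descriptive tabulation of the gastric-polyp cohort (worked example).

The bundled tables transcribe a retrospective cohort of 111 patients with
endoscopically detected gastric polyps, cross-classified by histological
type against age band, maximum polyp diameter, and anatomical location.
Histological classes: hyperplastic, inflammatory, fundic-gland,
metaplastic, hamartoma, adenomatous, and gastric (adeno)carcinoma; the
first five are non-neoplastic, the last two neoplastic.  This module
validates the tables and reproduces the marginal counts and percentage
distributions (percentages over patients, rounded half-up to 1 decimal).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources

import numpy as np
import pandas as pd

from .errors import DataValidationError, ParameterError

HISTOLOGY_LABELS = (
    "hyperplastic",
    "inflammatory",
    "fundic_gland",
    "metaplastic",
    "hamartoma",
    "adenomatous",
    "gastric_cancer",
)
NON_NEOPLASTIC = HISTOLOGY_LABELS[:5]
NEOPLASTIC = HISTOLOGY_LABELS[5:]

N_PATIENTS = 111

BUNDLED_TABLES = {
    "age": "table1_age.csv",
    "size": "table2_size.csv",
    "location": "table3_location.csv",
}


@dataclass
class CohortTable:
    """Histology x stratum contingency table of patient counts."""

    strata: tuple[str, ...]
    histologies: tuple[str, ...]
    counts: np.ndarray  # (n_strata, n_histologies), non-negative ints
    n_patients: int = N_PATIENTS

    @property
    def grand_total(self) -> int:
        return int(self.counts.sum())


def round_half_up(x: float, decimals: int = 1) -> float:
    """Round half away from zero at the given decimal (5s round up)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def load_table(path, n_patients: int = N_PATIENTS) -> CohortTable:
    """Read and validate a cohort CSV (header = histologies, rows = strata).

    Every cell must be a non-negative integer, every column label a known
    histology, and the grand total must equal the cohort size; violations
    raise :class:`DataValidationError` naming the offending cell.
    """
    try:
        df = pd.read_csv(path, index_col=0)
    except (pd.errors.EmptyDataError, pd.errors.ParserError) as exc:
        raise DataValidationError(f"{path}: unreadable table ({exc})") from exc
    if df.empty:
        raise DataValidationError(f"{path}: table has no data rows")
    for col in df.columns:
        if col not in HISTOLOGY_LABELS:
            raise DataValidationError(
                f"{path}: unknown histology column {col!r}; "
                f"expected one of {HISTOLOGY_LABELS}"
            )
    counts = np.zeros(df.shape, dtype=np.int64)
    for i, stratum in enumerate(df.index):
        for j, col in enumerate(df.columns):
            cell = df.iloc[i, j]
            try:
                val = int(cell)
                if val != float(cell) or val < 0:
                    raise ValueError
            except (TypeError, ValueError):
                raise DataValidationError(
                    f"{path}: cell ({stratum!r}, {col!r}) = {cell!r} "
                    "is not a non-negative integer"
                ) from None
            counts[i, j] = val
    total = int(counts.sum())
    if total != n_patients:
        raise DataValidationError(
            f"{path}: grand total {total} != expected cohort size {n_patients}"
        )
    return CohortTable(
        strata=tuple(str(s) for s in df.index),
        histologies=tuple(df.columns),
        counts=counts,
        n_patients=n_patients,
    )


def load_bundled_table(name: str) -> CohortTable:
    """Load one of the packaged cohort tables: 'age', 'size' or 'location'."""
    if name not in BUNDLED_TABLES:
        raise ParameterError(
            f"unknown table {name!r}; choose from {sorted(BUNDLED_TABLES)}"
        )
    ref = resources.files("endostitch") / "data" / BUNDLED_TABLES[name]
    with resources.as_file(ref) as path:
        return load_table(path)


def marginal(table: CohortTable, axis: str) -> dict[str, tuple[int, float]]:
    """Marginal counts and percentages along 'rows' (strata) or 'columns'.

    Percentages are 100 * count / grand_total, rounded half-up to one
    decimal, matching the convention of clinical tabulations.
    """
    if axis == "rows":
        labels, sums = table.strata, table.counts.sum(axis=1)
    elif axis == "columns":
        labels, sums = table.histologies, table.counts.sum(axis=0)
    else:
        raise ParameterError(f"axis must be 'rows' or 'columns', got {axis!r}")
    total = table.grand_total
    return {
        label: (int(c), round_half_up(100.0 * int(c) / total))
        for label, c in zip(labels, sums)
    }


def singleness_summary(
    single: int, multiple: int, n_patients: int = N_PATIENTS
) -> dict[str, tuple[int, float]]:
    """Two-category summary of single- vs multiple-polyp patients."""
    if single < 0 or multiple < 0:
        raise ParameterError("counts must be non-negative")
    if single + multiple != n_patients:
        raise DataValidationError(
            f"single + multiple = {single + multiple} != cohort size {n_patients}"
        )
    total = single + multiple
    return {
        "single": (single, round_half_up(100.0 * single / total)),
        "multiple": (multiple, round_half_up(100.0 * multiple / total)),
    }


def summary_to_text(summary: dict[str, tuple[int, float]]) -> str:
    """Aligned plain-text rendering of a distribution summary."""
    width = max(len(k) for k in summary)
    lines = [
        f"{label:<{width}}  {count:>4d}  {pct:>5.1f}%"
        for label, (count, pct) in summary.items()
    ]
    return "\n".join(lines)
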