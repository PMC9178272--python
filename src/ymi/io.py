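"""Reading, validating and writing per-fly cohort tables.

The released Y-maze dataset is a flat table, one row per fly, whose
columns combine the three behavioral measures (``handedness``,
``numTurns``, ``switchiness``), their group-wise Levene transforms
(``lev_*``), and experimental metadata (genotype, rearing/treatment
condition, temperature, experimenter, hardware identifiers, sex, and
the state of the *white* locus).  This module reads and writes tables
in that schema (CSV or Parquet), validates row-level invariants, and
summarizes metadata composition.

Column-name matching is case-insensitive; the mapping actually applied
is recorded on the returned :class:`CohortTable`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "TABLE_COLUMNS",
    "MANDATORY_COLUMNS",
    "CATEGORICAL_COLUMNS",
    "CohortTable",
    "SchemaError",
    "read_cohort",
    "write_cohort",
    "validate_cohort",
    "summarize_metadata",
]

#: Canonical column order of the released per-fly table.
TABLE_COLUMNS = (
    "flyID",
    "handedness",
    "numTurns",
    "switchiness",
    "lev_handedness",
    "lev_numTurns",
    "lev_switchiness",
    "genotype",
    "expCond",
    "expTemp",
    "age",
    "experimenterID",
    "trayID",
    "boxID",
    "date",
    "arrayFormat",
    "mazeNum",
    "acquisition",
    "analysis",
    "sex",
    "eyeColor",
)

MANDATORY_COLUMNS = ("handedness", "numTurns", "genotype")

CATEGORICAL_COLUMNS = (
    "genotype",
    "expCond",
    "experimenterID",
    "trayID",
    "boxID",
    "date",
    "arrayFormat",
    "mazeNum",
    "acquisition",
    "analysis",
    "sex",
    "eyeColor",
)

NUMERIC_COLUMNS = (
    "handedness",
    "numTurns",
    "switchiness",
    "lev_handedness",
    "lev_numTurns",
    "lev_switchiness",
    "expTemp",
    "age",
)

SEX_LEVELS = frozenset({"male", "female", "both"})

#: Six states of the white locus: wild type (+), mini-white transgene
#: (+mw.hs) and null (−) alleles, in homo/heterozygous combination.
EYE_COLOR_LEVELS = frozenset(
    {"+/+", "+/+mw.hs", "+/-", "+mw.hs/+mw.hs", "+mw.hs/-", "-/-"}
)

_INTEGRALITY_TOL = 1e-6


class SchemaError(ValueError):
    """The table is structurally incompatible with the expected schema."""


@dataclass
class CohortTable:
    """A validated per-fly table plus provenance.

    Wraps a :class:`pandas.DataFrame` whose columns follow the released
    schema (extra columns are carried through untouched).
    """

    df: pd.DataFrame
    provenance: str = ""
    column_mapping: dict = field(default_factory=dict)
    validation_report: pd.DataFrame | None = None

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other) -> bool:  # field-for-field comparison
        if not isinstance(other, CohortTable):
            return NotImplemented
        try:
            pd.testing.assert_frame_equal(
                self.df.reset_index(drop=True),
                other.df.reset_index(drop=True),
                check_dtype=False,
                atol=1e-12,
                rtol=0,
            )
        except AssertionError:
            return False
        return True


def _canonicalize_columns(df: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Map case-insensitive header matches onto canonical Table names."""
    lower_to_canonical = {c.lower(): c for c in TABLE_COLUMNS}
    mapping = {}
    for col in df.columns:
        canonical = lower_to_canonical.get(str(col).lower())
        if canonical is not None and canonical != col:
            mapping[col] = canonical
    if mapping:
        logger.info("column name mapping applied: %s", mapping)
        df = df.rename(columns=mapping)
    return df, mapping


def validate_cohort(df: pd.DataFrame, strict: str = "warn") -> tuple[pd.DataFrame, pd.DataFrame]:
    """Check row-level invariants; return (table, issue report).

    Invariants: handedness ∈ [0,1]; numTurns a non-negative integer;
    switchiness and lev_* non-negative where present; handedness ×
    numTurns integral (the bias must be a realizable fraction of the
    turn count); sex and eyeColor drawn from their controlled
    vocabularies; flyID unique.

    ``strict`` is one of ``"warn"`` (default: report and keep offending
    rows, matching use of all records in grand analyses), ``"drop"``
    (remove them) or ``"error"`` (raise).
    """
    if strict not in ("warn", "drop", "error"):
        raise ValueError("strict must be 'warn', 'drop' or 'error'")
    issues: list[tuple[int, str, str]] = []

    def flag(index, column, problem):
        issues.extend((int(i), column, problem) for i in index)

    if "handedness" in df:
        h = pd.to_numeric(df["handedness"], errors="coerce")
        bad = df.index[(h < 0) | (h > 1)]
        flag(bad, "handedness", "outside [0, 1]")
    if "numTurns" in df:
        n = pd.to_numeric(df["numTurns"], errors="coerce")
        flag(df.index[n < 0], "numTurns", "negative")
        nonint = n.notna() & (np.abs(n - np.round(n)) > _INTEGRALITY_TOL)
        flag(df.index[nonint], "numTurns", "not an integer")
        if "handedness" in df:
            prod = h * n
            ok = h.notna() & n.notna()
            bad = ok & (np.abs(prod - np.round(prod)) > max(_INTEGRALITY_TOL, 1e-9) * np.maximum(n, 1))
            flag(df.index[bad], "handedness", "handedness × numTurns not integral")
    for col in ("switchiness", "lev_handedness", "lev_numTurns", "lev_switchiness"):
        if col in df:
            v = pd.to_numeric(df[col], errors="coerce")
            flag(df.index[v < 0], col, "negative")
    if "sex" in df:
        s = df["sex"].astype("string").str.lower()
        bad = s.notna() & ~s.isin(SEX_LEVELS)
        flag(df.index[bad], "sex", "not in {male, female, both}")
    if "eyeColor" in df:
        e = df["eyeColor"].astype("string")
        bad = e.notna() & ~e.isin(EYE_COLOR_LEVELS)
        flag(df.index[bad], "eyeColor", "unknown white-locus state")
    if "flyID" in df:
        dup = df["flyID"].duplicated(keep=False) & df["flyID"].notna()
        flag(df.index[dup], "flyID", "duplicate id")

    report = pd.DataFrame(issues, columns=["row", "column", "problem"])
    if len(report):
        if strict == "error":
            raise SchemaError(
                f"{len(report)} validation issue(s); first: "
                f"row {report.iloc[0]['row']} {report.iloc[0]['column']}: "
                f"{report.iloc[0]['problem']}"
            )
        if strict == "drop":
            df = df.drop(index=report["row"].unique())
            logger.warning("dropped %d invalid row(s)", report["row"].nunique())
        else:
            logger.warning("%d validation issue(s) in %d row(s); rows kept",
                           len(report), report["row"].nunique())
    return df, report


def _infer_format(path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    return "parquet" if str(path).endswith((".parquet", ".pq")) else "csv"


def read_cohort(path, fmt: str | None = None, strict: str = "warn") -> CohortTable:
    """Read and validate a per-fly table (CSV or Parquet).

    Raises :class:`SchemaError` if any mandatory column (handedness,
    numTurns, genotype) is absent after case-insensitive matching.
    """
    fmt = _infer_format(path, fmt)
    if fmt == "csv":
        df = pd.read_csv(path)
    elif fmt == "parquet":
        df = pd.read_parquet(path)
    else:
        raise ValueError(f"unknown format: {fmt!r}")
    df, mapping = _canonicalize_columns(df)
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"mandatory column(s) missing: {missing}")
    for col in NUMERIC_COLUMNS:
        if col in df.columns and not pd.api.types.is_numeric_dtype(df[col]):
            coerced = pd.to_numeric(df[col], errors="coerce")
            newly_missing = coerced.isna() & df[col].notna()
            if newly_missing.any():
                logger.warning(
                    "%s: %d unparseable numeric value(s) set to missing",
                    col, int(newly_missing.sum()),
                )
            df[col] = coerced
    df, report = validate_cohort(df, strict=strict)
    return CohortTable(
        df=df.reset_index(drop=True),
        provenance=str(path),
        column_mapping=mapping,
        validation_report=report,
    )


def write_cohort(table: CohortTable | pd.DataFrame, path, fmt: str | None = None) -> str:
    """Write a cohort table; read_cohort(write_cohort(t)) round-trips."""
    df = table.df if isinstance(table, CohortTable) else table
    fmt = _infer_format(path, fmt)
    if fmt == "csv":
        df.to_csv(path, index=False, encoding="utf-8")
    elif fmt == "parquet":
        df.to_parquet(path, index=False)
    else:
        raise ValueError(f"unknown format: {fmt!r}")
    return str(path)


def summarize_metadata(table: CohortTable | pd.DataFrame, variable: str) -> dict:
    """Counts of flies per level of a categorical metadata column.

    Missing values are counted under ``None`` so the counts always sum
    to the number of records.
    """
    df = table.df if isinstance(table, CohortTable) else table
    resolved = {c.lower(): c for c in df.columns}.get(variable.lower())
    if resolved is None:
        raise KeyError(f"unknown column: {variable!r}")
    counts = df[resolved].value_counts(dropna=False)
    return {
        (None if pd.isna(level) else level): int(c) for level, c in counts.items()
    }
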