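"""Reading, writing and role validation for tabular survival data.

Survival data arrive as plain-text tables: a header row of variable names
followed by one numeric row per subject.  Two dialects are supported:

``dat``
    whitespace-delimited columns (one or more spaces or tabs between
    fields), the traditional export format of spreadsheet tools;
``csv``
    comma-separated values (RFC-4180 subset, header required).

All columns are parsed as numbers.  The tokens ``NA``, ``.`` and the empty
field denote missing values.  Analysis requires a :class:`RoleAssignment`
mapping columns to the time, status and optional factor roles; rows with a
missing or non-finite value in a role column are dropped (with a reported
count) before estimation.
"""

from __future__ import annotations

import csv as _csv
import io
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SurvivalDataset",
    "RoleAssignment",
    "AnalysisInput",
    "FormatError",
    "ValidationError",
    "read_table",
    "write_table",
    "list_variables",
    "assign_roles",
]

#: Field tokens that parse as a missing value.
MISSING_TOKENS = frozenset({"NA", ".", ""})

DIALECTS = ("dat", "csv")


class FormatError(ValueError):
    """A file does not conform to the expected tabular text format."""


class ValidationError(ValueError):
    """A role assignment is inconsistent with the dataset contents."""


@dataclass(frozen=True)
class SurvivalDataset:
    """A rectangular table of named numeric columns, one row per subject.

    Parameters
    ----------
    data
        Numeric DataFrame; column order is the file column order.
    source_path
        Where the table was read from, if anywhere.
    """

    data: pd.DataFrame
    source_path: str | None = None

    def __post_init__(self) -> None:
        names = list(self.data.columns)
        if len(names) == 0:
            raise FormatError("a dataset needs at least one variable")
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise FormatError(f"duplicate variable names: {', '.join(map(str, dupes))}")
        if any(not str(n) for n in names):
            raise FormatError("variable names must be non-empty")

    @property
    def variable_names(self) -> list[str]:
        return [str(c) for c in self.data.columns]

    @property
    def n_rows(self) -> int:
        return len(self.data)

    @property
    def rows(self) -> np.ndarray:
        """The table as a float matrix (subjects x variables)."""
        return self.data.to_numpy(dtype=float)

    def column(self, name: str) -> np.ndarray:
        if name not in self.data.columns:
            raise KeyError(
                f"unknown variable {name!r}; available: {', '.join(self.variable_names)}"
            )
        return self.data[name].to_numpy(dtype=float)

    def subset(self, mask: np.ndarray) -> "SurvivalDataset":
        """Row subset preserving order; ``mask`` is a boolean vector."""
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != (self.n_rows,):
            raise ValueError(f"mask length {mask.shape} != n_rows {self.n_rows}")
        return SurvivalDataset(self.data.loc[mask].reset_index(drop=True),
                               source_path=self.source_path)

    def equals(self, other: "SurvivalDataset") -> bool:
        return (self.variable_names == other.variable_names
                and self.data.reset_index(drop=True).equals(other.data.reset_index(drop=True)))


@dataclass(frozen=True)
class RoleAssignment:
    """Maps dataset variables to analysis roles.

    ``time_var`` holds non-negative follow-up times (units arbitrary),
    ``status_var`` the event indicator, ``factor_var`` an optional discrete
    grouping variable (one survival curve per level).  ``event_code`` is the
    status value meaning "event observed"; every other finite status value is
    treated as censored (0/1 coding by default).
    """

    time_var: str
    status_var: str
    factor_var: str | None = None
    event_code: float = 1.0


@dataclass(frozen=True)
class AnalysisInput:
    """A validated dataset/roles bundle ready for estimation.

    ``n_dropped`` counts rows removed because a role column held a missing or
    non-finite value; ``dataset`` retains only the clean rows, in order.
    """

    dataset: SurvivalDataset
    roles: RoleAssignment
    n_dropped: int = 0

    @property
    def times(self) -> np.ndarray:
        return self.dataset.column(self.roles.time_var)

    @property
    def status(self) -> np.ndarray:
        """Boolean event indicator (True = event, False = censored)."""
        raw = self.dataset.column(self.roles.status_var)
        return raw == self.roles.event_code

    @property
    def factor_levels(self) -> list[float]:
        """Sorted distinct factor levels; ``[nan]``-free, one entry if no factor."""
        if self.roles.factor_var is None:
            return [1.0]
        vals = self.dataset.column(self.roles.factor_var)
        return sorted(set(vals.tolist()))

    def groups(self) -> list[tuple[float, np.ndarray, np.ndarray]]:
        """Per factor level, ``(level, times, status)`` in level order.

        Without a factor variable, a single stratum labelled 1 holds all rows.
        """
        t, s = self.times, self.status
        if self.roles.factor_var is None:
            return [(1.0, t, s)]
        f = self.dataset.column(self.roles.factor_var)
        return [(lv, t[f == lv], s[f == lv]) for lv in self.factor_levels]


def _parse_cell(token: str, line_no: int, col_name: str) -> float:
    token = token.strip()
    if token in MISSING_TOKENS:
        return math.nan
    try:
        return float(token)
    except ValueError:
        raise FormatError(
            f"line {line_no}: non-numeric value {token!r} in column {col_name!r}"
        ) from None


def _rows_from_lines(split_lines: Iterable[tuple[int, list[str]]],
                     header: list[str]) -> list[list[float]]:
    rows: list[list[float]] = []
    width = len(header)
    for line_no, fields in split_lines:
        if len(fields) != width:
            raise FormatError(
                f"line {line_no}: expected {width} fields, found {len(fields)}"
            )
        rows.append([_parse_cell(tok, line_no, header[j]) for j, tok in enumerate(fields)])
    return rows


def read_table(path: str | Path, dialect: str = "dat") -> SurvivalDataset:
    """Read a survival table from ``path``.

    The first line is the header of variable names; every following
    non-blank line is one subject.  ``dialect`` selects ``"dat"``
    (whitespace-separated; any run of spaces/tabs is one separator) or
    ``"csv"``.

    Raises
    ------
    FileNotFoundError
        if ``path`` does not exist.
    FormatError
        for ragged rows, non-numeric cells (both reported with their line
        number) or duplicate header names.
    """
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; choose from {DIALECTS}")
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if dialect == "dat":
        raw = [(i + 1, ln.split()) for i, ln in enumerate(text.splitlines())
               if ln.strip()]
    else:
        reader = _csv.reader(io.StringIO(text))
        raw = [(i + 1, [f.strip() for f in rec]) for i, rec in enumerate(reader)
               if any(f.strip() for f in rec)]
    if not raw:
        raise FormatError(f"{path}: empty file, expected a header line")
    header = [str(t) for t in raw[0][1]]
    rows = _rows_from_lines(raw[1:], header)
    frame = pd.DataFrame(rows, columns=header, dtype=float)
    return SurvivalDataset(frame, source_path=str(path))


def write_table(ds: SurvivalDataset, path: str | Path, dialect: str = "dat") -> Path:
    """Write ``ds`` so that :func:`read_table` reproduces it exactly.

    Values are written with :func:`repr`-faithful formatting (shortest
    decimal round-tripping the float); missing values become ``NA``.
    """
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; choose from {DIALECTS}")
    path = Path(path)
    sep = " " if dialect == "dat" else ","

    def fmt(v: float) -> str:
        if math.isnan(v):
            return "NA"
        if float(v).is_integer() and abs(v) < 1e15:
            return str(int(v))
        return repr(float(v))

    lines = [sep.join(ds.variable_names)]
    for row in ds.data.itertuples(index=False):
        lines.append(sep.join(fmt(v) for v in row))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


def list_variables(ds: SurvivalDataset) -> list[str]:
    """Variable names in file column order."""
    return ds.variable_names


def assign_roles(ds: SurvivalDataset, roles: RoleAssignment) -> AnalysisInput:
    """Validate roles against ``ds`` and return the cleaned analysis bundle.

    Rows with missing or non-finite time/status (or factor, if assigned) are
    dropped; the count is recorded on the result.  Negative times, a status
    column with more than 10 distinct values (almost certainly the wrong
    column) and a factor equal to the time or status column are rejected.
    """
    for var in (roles.time_var, roles.status_var):
        if var not in ds.variable_names:
            raise ValidationError(
                f"role variable {var!r} not in dataset "
                f"(available: {', '.join(ds.variable_names)})"
            )
    if roles.time_var == roles.status_var:
        raise ValidationError("time and status variables must differ")
    if roles.factor_var is not None:
        if roles.factor_var not in ds.variable_names:
            raise ValidationError(f"factor variable {roles.factor_var!r} not in dataset")
        if roles.factor_var in (roles.time_var, roles.status_var):
            raise ValidationError("factor variable must differ from time and status")

    role_cols = [roles.time_var, roles.status_var]
    if roles.factor_var is not None:
        role_cols.append(roles.factor_var)
    finite = np.ones(ds.n_rows, dtype=bool)
    for col in role_cols:
        finite &= np.isfinite(ds.column(col))
    n_dropped = int(ds.n_rows - finite.sum())
    clean = ds.subset(finite) if n_dropped else ds

    if clean.n_rows == 0:
        raise ValidationError("no rows remain after dropping missing role values")
    t = clean.column(roles.time_var)
    if (t < 0).any():
        raise ValidationError(f"time variable {roles.time_var!r} contains negative values")
    status_levels = np.unique(clean.column(roles.status_var))
    if status_levels.size > 10:
        raise ValidationError(
            f"status variable {roles.status_var!r} has {status_levels.size} distinct "
            "values; this does not look like an event indicator"
        )
    if roles.factor_var is not None:
        k = np.unique(clean.column(roles.factor_var)).size
        if not 1 <= k <= 50:
            raise ValidationError(
                f"factor variable {roles.factor_var!r} has {k} levels (allowed: 1..50)"
            )
    return AnalysisInput(dataset=clean, roles=roles, n_dropped=n_dropped)
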