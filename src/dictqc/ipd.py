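"""Profiling of individual-participant-data (IPD) tables and dictionary
inference.

Some shared studies provide row-level data but no (or an incomplete)
dictionary.  This module profiles each data column — distinct-value count,
maximum token length, inferred type — and can build a full element
dictionary from the data alone, using the table name as the group ID, which
mirrors how studies that organize elements by data table label their groups.

Type inference is deliberately conservative and format-driven:

* numeric: integer/decimal/scientific notation with optional sign; tokens
  with a leading zero followed by more digits ("007") are treated as
  ID-like strings by default;
* date: ISO 8601, YYYYMMDD, MM/DD/YYYY or DD-MON-YYYY;
* datetime: a recognized date plus a time component.

A column is typed date/datetime/numeric only if *every* non-missing value
parses; otherwise it is a string.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from datetime import datetime
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from .model import (
    DataElement,
    DataType,
    SourceFormat,
    StudyDictionary,
    normalize_token,
)

__all__ = [
    "IPDTable",
    "ValueProfile",
    "DuplicateColumnError",
    "MISSING_TOKENS",
    "profile_column",
    "profile_tables",
    "infer_element_dictionary",
    "read_ipd_table",
    "read_ipd_dir",
    "is_missing",
    "is_numeric_token",
    "is_date_token",
    "is_datetime_token",
]

MISSING_TOKENS = frozenset({"", "na", "n/a", "."})

_NUMERIC_RE = re.compile(r"^[+-]?(\d+(\.\d*)?|\.\d+)([eE][+-]?\d+)?$")
_LEADING_ZERO_RE = re.compile(r"^[+-]?0\d")

_DATE_FORMATS = ("%Y-%m-%d", "%m/%d/%Y", "%d-%b-%Y")
_DATETIME_FORMATS = (
    "%Y-%m-%dT%H:%M:%S",
    "%Y-%m-%d %H:%M:%S",
    "%Y-%m-%dT%H:%M",
    "%Y-%m-%d %H:%M",
    "%m/%d/%Y %H:%M:%S",
    "%m/%d/%Y %H:%M",
)


class DuplicateColumnError(ValueError):
    """An IPD table carries two columns with the same normalized ID."""


def is_missing(token: Optional[str]) -> bool:
    return token is None or token.strip().casefold() in MISSING_TOKENS


def is_numeric_token(token: str, leading_zero_is_string: bool = True) -> bool:
    token = token.strip()
    if not _NUMERIC_RE.match(token):
        return False
    if leading_zero_is_string and _LEADING_ZERO_RE.match(token):
        return False
    return True


def _parse_any(token: str, formats: Sequence[str]) -> bool:
    for fmt in formats:
        try:
            datetime.strptime(token, fmt)
            return True
        except ValueError:
            continue
    return False


def is_date_token(token: str) -> bool:
    token = token.strip()
    if len(token) == 8 and token.isdigit():
        return _parse_any(token, ("%Y%m%d",))
    return _parse_any(token, _DATE_FORMATS)


def is_datetime_token(token: str) -> bool:
    return _parse_any(token.strip(), _DATETIME_FORMATS)


@dataclass
class ValueProfile:
    """Per-column IPD summary."""

    n_total: int
    n_nonmissing: int
    n_distinct: int
    max_length: int
    inferred_type: DataType
    distinct_values: Optional[list[str]] = None  # retained only when small

    def __post_init__(self) -> None:
        if not (self.n_distinct <= self.n_nonmissing <= self.n_total):
            raise ValueError("inconsistent profile counts")
        if self.n_nonmissing > 0 and self.max_length < 1:
            raise ValueError("max_length must be >= 1 with non-missing values")


def profile_column(
    values: Iterable[str],
    retention_cap: int = 200,
    leading_zero_is_string: bool = True,
) -> ValueProfile:
    """Profile one data column.

    The inferred type is datetime if every non-missing token parses as a
    date-time, else date, else numeric, else string; ``unknown`` when the
    column has no non-missing values.  Counts are always exact; the distinct
    set itself is retained only when its size is at most ``retention_cap``.
    """
    n_total = 0
    n_nonmissing = 0
    distinct: set[str] = set()
    max_length = 0
    all_numeric = all_date = all_datetime = True
    for raw in values:
        n_total += 1
        if is_missing(raw):
            continue
        n_nonmissing += 1
        token = str(raw).strip()
        distinct.add(token)
        max_length = max(max_length, len(token))
        if all_datetime and not is_datetime_token(token):
            all_datetime = False
        if all_date and not is_date_token(token):
            all_date = False
        if all_numeric and not is_numeric_token(token, leading_zero_is_string):
            all_numeric = False
    if n_nonmissing == 0:
        inferred = DataType.UNKNOWN
    elif all_datetime:
        inferred = DataType.DATETIME
    elif all_date:
        inferred = DataType.DATE
    elif all_numeric:
        inferred = DataType.NUMERIC
    else:
        inferred = DataType.STRING
    return ValueProfile(
        n_total=n_total,
        n_nonmissing=n_nonmissing,
        n_distinct=len(distinct),
        max_length=max_length,
        inferred_type=inferred,
        distinct_values=sorted(distinct) if len(distinct) <= retention_cap else None,
    )


@dataclass
class IPDTable:
    """One IPD data table: ordered columns of raw text tokens."""

    table_name: str
    column_ids: list[str]
    values: dict[str, list[str]]

    def check_unique_columns(self) -> None:
        keys = [normalize_token(c) for c in self.column_ids]
        if len(set(keys)) != len(keys):
            dupes = sorted({k for k in keys if keys.count(k) > 1})
            raise DuplicateColumnError(
                f"table {self.table_name!r} has duplicate column IDs: {dupes}"
            )


def read_ipd_table(path: Path | str) -> IPDTable:
    """Read one IPD CSV; the file stem becomes the table name."""
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8-sig")
    return IPDTable(
        table_name=path.stem,
        column_ids=[str(c) for c in df.columns],
        values={str(c): df[c].tolist() for c in df.columns},
    )


def read_ipd_dir(directory: Path | str) -> list[IPDTable]:
    """Read every ``*.csv`` in a directory as an IPD table (sorted order)."""
    directory = Path(directory)
    return [read_ipd_table(p) for p in sorted(directory.glob("*.csv"))]


def profile_tables(
    tables: Sequence[IPDTable], retention_cap: int = 200
) -> dict[str, ValueProfile]:
    """Profiles keyed by normalized column ID (first table wins on repeats)."""
    out: dict[str, ValueProfile] = {}
    for table in tables:
        for col in table.column_ids:
            key = normalize_token(col)
            if key not in out:
                out[key] = profile_column(table.values[col], retention_cap)
    return out


def infer_element_dictionary(
    tables: Sequence[IPDTable], study_id: str
) -> StudyDictionary:
    """Build an element dictionary from IPD tables alone.

    One element per (table, column) pair: the table name is the group ID,
    the profiled type and maximum length fill the type/length attributes,
    and descriptions are left empty (data cannot supply them).  The raw type
    token is set to the inferred canonical token.
    """
    if not tables:
        raise ValueError("at least one IPD table is required")
    elements: list[DataElement] = []
    for table in tables:
        table.check_unique_columns()
        for col in table.column_ids:
            prof = profile_column(table.values[col])
            elements.append(
                DataElement(
                    study_id=study_id,
                    element_id=col,
                    description="",
                    raw_type=(
                        prof.inferred_type.value
                        if prof.inferred_type is not DataType.UNKNOWN
                        else None
                    ),
                    data_type=prof.inferred_type,
                    length=prof.max_length if prof.n_nonmissing > 0 else None,
                    group_id=table.table_name,
                )
            )
    return StudyDictionary(
        study_id=study_id,
        elements=elements,
        source_format=SourceFormat.INFERRED_FROM_IPD,
        n_source_files=0,
    )
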