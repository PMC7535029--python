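"""Domain model for clinical-study data dictionaries.

A shared study is described here by three dictionary kinds:

* an **element dictionary** listing every data element (variable) with up to
  five attributes — description, element ID, data type, length, and group
  (case report form) ID — the "target data-element model";
* a **forms dictionary** listing case-report-form group IDs and titles;
* a **permissible-value dictionary** listing, one row per value, the allowed
  responses of categorical elements, linked back by element ID.

This module holds the dataclasses for those records, the canonical data-type
vocabulary with its synonym normalization, and the single percentage/rounding
rule used by every downstream metric.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from enum import Enum
from typing import Iterable, Mapping, Optional

logger = logging.getLogger(__name__)

__all__ = [
    "DataType",
    "SourceFormat",
    "DataElement",
    "FormEntry",
    "PermissibleValue",
    "StudyDictionary",
    "UndefinedRatioError",
    "DEFAULT_TYPE_SYNONYMS",
    "normalize_data_type",
    "normalize_token",
    "normalize_text",
    "percent",
    "round_ratio",
    "FLAG_STRING_CATEGORICAL",
    "FLAG_NUMERIC_CATEGORICAL",
    "FLAG_DESCRIPTION_IDENTICAL",
    "FLAG_MISSING_IN_DICTIONARY",
]


class DataType(str, Enum):
    """Canonical data types for a data element.

    ``categorical`` is never produced by :func:`normalize_data_type` — in
    shared dictionaries categorical variables are invariably declared as plain
    strings or numbers; the flag is assigned only by quality assessment or by
    explicit permissible-value linkage.
    """

    STRING = "string"
    NUMERIC = "numeric"
    DATE = "date"
    DATETIME = "datetime"
    CATEGORICAL = "categorical"
    UNKNOWN = "unknown"

    def __str__(self) -> str:  # serialize as the lowercase token
        return self.value


class SourceFormat(str, Enum):
    CSV_SINGLE = "csv_single"
    CSV_MULTI = "csv_multi"
    PDF = "pdf"
    MIXED = "mixed"
    INFERRED_FROM_IPD = "inferred_from_ipd"

    def __str__(self) -> str:
        return self.value


# Element-level quality flags.
FLAG_STRING_CATEGORICAL = "string_categorical_candidate"
FLAG_NUMERIC_CATEGORICAL = "numeric_categorical_candidate"
FLAG_DESCRIPTION_IDENTICAL = "description_identical_to_name"
FLAG_MISSING_IN_DICTIONARY = "missing_in_dictionary"

#: Default raw-token → canonical type synonyms.  Extensible via the
#: ``synonyms`` argument of :func:`normalize_data_type` (merged on top).
#: ``enumerated``/``boolean`` tokens are possible in the wild but are not
#: mapped by default; supply a custom table to enable them.
DEFAULT_TYPE_SYNONYMS: dict[str, DataType] = {
    "char": DataType.STRING,
    "character": DataType.STRING,
    "string": DataType.STRING,
    "text": DataType.STRING,
    "varchar": DataType.STRING,
    "number": DataType.NUMERIC,
    "numeric": DataType.NUMERIC,
    "num": DataType.NUMERIC,
    "int": DataType.NUMERIC,
    "integer": DataType.NUMERIC,
    "float": DataType.NUMERIC,
    "decimal": DataType.NUMERIC,
    "date": DataType.DATE,
    "datetime": DataType.DATETIME,
    "date-time": DataType.DATETIME,
    "date time": DataType.DATETIME,
    "timestamp": DataType.DATETIME,
}

_WS = re.compile(r"\s+")


def normalize_token(text: Optional[str]) -> str:
    """Canonical form of an identifier token: stripped and casefolded."""
    if text is None:
        return ""
    return text.strip().casefold()


def normalize_text(text: Optional[str]) -> str:
    """Canonical form of free text: casefolded, whitespace collapsed."""
    if text is None:
        return ""
    return _WS.sub(" ", text.strip()).casefold()


def normalize_data_type(
    raw_type: Optional[str],
    synonyms: Optional[Mapping[str, DataType]] = None,
) -> DataType:
    """Map a raw data-type token onto the canonical type vocabulary.

    Total function: empty/absent tokens and unmappable tokens both yield
    ``unknown`` (the latter with a logged warning).  Matching is
    case-insensitive via a configurable synonym table.
    """
    token = normalize_token(raw_type)
    if not token:
        return DataType.UNKNOWN
    table = dict(DEFAULT_TYPE_SYNONYMS)
    if synonyms:
        table.update({normalize_token(k): DataType(v) for k, v in synonyms.items()})
    mapped = table.get(token)
    if mapped is None:
        logger.warning("unmappable data type token %r -> unknown", raw_type)
        return DataType.UNKNOWN
    return mapped


class UndefinedRatioError(ZeroDivisionError):
    """A percentage or mean was requested with a zero denominator."""


def percent(numerator: int, denominator: int, decimals: int = 1) -> float:
    """``100 * numerator / denominator`` rounded half-up to ``decimals``.

    Half-up (not banker's) rounding is the house rule for every reported
    percentage, e.g. 9945/10755 = 92.468% → 92.5 and 1511/1815 = 83.2507%
    → 83.3.  A zero denominator raises :class:`UndefinedRatioError` rather
    than silently returning 0.
    """
    if denominator <= 0:
        raise UndefinedRatioError(
            f"percentage undefined: {numerator}/{denominator}"
        )
    if decimals < 0:
        raise ValueError("decimals must be >= 0")
    q = Decimal(1).scaleb(-decimals)
    value = (Decimal(numerator) * 100 / Decimal(denominator)).quantize(
        q, rounding=ROUND_HALF_UP
    )
    return float(value)


def round_ratio(numerator: float, denominator: float, decimals: int = 2) -> float:
    """``numerator / denominator`` rounded half-up (used for means)."""
    if denominator == 0:
        raise UndefinedRatioError(f"ratio undefined: {numerator}/{denominator}")
    q = Decimal(1).scaleb(-decimals)
    value = (Decimal(str(numerator)) / Decimal(str(denominator))).quantize(
        q, rounding=ROUND_HALF_UP
    )
    return float(value)


@dataclass
class DataElement:
    """One row of the target data-element model."""

    study_id: str
    element_id: str
    description: str = ""
    raw_type: Optional[str] = None
    data_type: Optional[DataType] = None
    length: Optional[int] = None
    group_id: Optional[str] = None
    flags: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.element_id = (self.element_id or "").strip()
        if not self.element_id:
            raise ValueError("element_id must be non-empty")
        if self.data_type is None:
            self.data_type = normalize_data_type(self.raw_type)
        else:
            self.data_type = DataType(self.data_type)
        if self.length is not None:
            self.length = int(self.length)
            if self.length < 1:
                raise ValueError(
                    f"length must be >= 1 for element {self.element_id!r}"
                )
        if self.description is None:
            self.description = ""
        if self.description and normalize_text(self.description) == normalize_text(
            self.element_id
        ):
            self.flags.add(FLAG_DESCRIPTION_IDENTICAL)
        else:
            self.flags.discard(FLAG_DESCRIPTION_IDENTICAL)

    @property
    def has_description(self) -> bool:
        return bool(self.description.strip())

    @property
    def key(self) -> str:
        return normalize_token(self.element_id)


@dataclass
class FormEntry:
    """One case report form (or element group) of a forms dictionary."""

    study_id: str
    group_id: str
    title: str = ""
    harmonized_name: Optional[str] = None
    copyrighted: bool = False

    def __post_init__(self) -> None:
        self.group_id = (self.group_id or "").strip()
        if not self.group_id:
            raise ValueError("group_id must be non-empty")
        if self.title is None:
            self.title = ""


@dataclass
class PermissibleValue:
    """One allowed response of a categorical data element."""

    study_id: str
    element_id: str
    value: str = ""
    value_id: Optional[str] = None
    description: Optional[str] = None

    def __post_init__(self) -> None:
        self.element_id = (self.element_id or "").strip()
        if not self.element_id:
            raise ValueError("permissible value must carry an element_id")
        if not (self.value or "").strip() and not (self.description or "").strip():
            raise ValueError(
                f"permissible value for {self.element_id!r} needs a value "
                "or a description"
            )

    @property
    def element_key(self) -> str:
        return normalize_token(self.element_id)


@dataclass
class StudyDictionary:
    """A study's three dictionaries plus provenance."""

    study_id: str
    elements: list[DataElement] = field(default_factory=list)
    forms: list[FormEntry] = field(default_factory=list)
    permissible_values: list[PermissibleValue] = field(default_factory=list)
    source_format: SourceFormat = SourceFormat.CSV_SINGLE
    n_source_files: int = 1

    def element_keys(self) -> set[str]:
        """Normalized element IDs (the ID-matching rule: case-insensitive,
        whitespace-stripped, exact otherwise)."""
        return {e.key for e in self.elements}

    def pvs_by_element(self) -> dict[str, list[PermissibleValue]]:
        out: dict[str, list[PermissibleValue]] = {}
        for pv in self.permissible_values:
            out.setdefault(pv.element_key, []).append(pv)
        return out


def flags_to_str(flags: Iterable[str]) -> str:
    """Serialize a flag set as semicolon-joined sorted tokens ('' if none)."""
    return ";".join(sorted(flags))


def flags_from_str(text: Optional[str]) -> set[str]:
    if not text or not text.strip():
        return set()
    return {t for t in (s.strip() for s in text.split(";")) if t}
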