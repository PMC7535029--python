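"""Reading and writing the three dictionary kinds from/to CSV.

Shared studies export their dictionaries with wildly heterogeneous column
headers ("Data Element ID", "variable name", "DE short label" ...), as a
single CSV or split across many files, sometimes with BOMs or non-comma
delimiters.  This module maps those variants onto the target data-element
model via a configurable :class:`HeaderMap`, concatenates split dictionaries,
and writes/reads the aggregate data-elements file.

PDF dictionaries exist in the wild but are rejected with a distinct error
code: extracting them is a manual conversion task, not a parsing one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from .model import (
    DataElement,
    DataType,
    FormEntry,
    PermissibleValue,
    SourceFormat,
    StudyDictionary,
    flags_from_str,
    flags_to_str,
    normalize_data_type,
    normalize_token,
)

logger = logging.getLogger(__name__)

__all__ = [
    "HeaderMap",
    "DEFAULT_HEADER_MAP",
    "DEFAULT_MISSING_TOKENS",
    "DictionaryIOError",
    "UnreadableDictionaryError",
    "UnsupportedFormatError",
    "read_element_dictionary",
    "read_forms_dictionary",
    "read_pv_dictionary",
    "write_aggregate_elements",
    "read_aggregate_elements",
    "load_example_elements",
    "load_example_forms",
    "load_example_pvs",
    "fixture_path",
]

#: Tokens treated as absent values (compared case-insensitively).
DEFAULT_MISSING_TOKENS = frozenset({"", "na", "n/a", "."})


class DictionaryIOError(Exception):
    """Base error for dictionary reading/writing."""


class UnreadableDictionaryError(DictionaryIOError):
    """A dictionary file lacks a resolvable required column."""

    def __init__(self, message: str, file: Optional[str] = None):
        super().__init__(message)
        self.file = file


class UnsupportedFormatError(DictionaryIOError):
    """Non-machine-readable dictionary format (e.g. PDF)."""

    def __init__(self, message: str, code: str = "unsupported_format"):
        super().__init__(message)
        self.code = code


def _norm_header(name: str) -> str:
    return " ".join(str(name).replace("_", " ").replace("-", " ").split()).casefold()


@dataclass
class HeaderMap:
    """Role → header-name aliases, compared case-insensitively.

    Roles cover the element dictionary (element_id, description, data_type,
    length, group_id), the forms dictionary (group_id, form_title) and the
    permissible-value dictionary (pv_*).  Users extend the defaults with
    :meth:`extended` rather than rebuilding the table.
    """

    aliases: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.aliases = {
            role: [_norm_header(a) for a in names]
            for role, names in self.aliases.items()
        }
        for role, names in self.aliases.items():
            if not names:
                raise ValueError(f"header role {role!r} has no aliases")

    def extended(self, extra: dict[str, list[str]]) -> "HeaderMap":
        merged = {r: list(a) for r, a in self.aliases.items()}
        for role, names in extra.items():
            merged.setdefault(role, [])
            # user aliases take precedence
            merged[role] = [_norm_header(n) for n in names] + merged[role]
        return HeaderMap(merged)

    def resolve(self, columns: Sequence[str], roles: Sequence[str]) -> dict[str, str]:
        """Resolve each role to an actual column name, first alias match wins.

        Resolution is by header name only, never by position; a column
        already claimed by an earlier role is not reused.
        """
        normed = {_norm_header(c): c for c in columns}
        out: dict[str, str] = {}
        claimed: set[str] = set()
        for role in roles:
            for alias in self.aliases.get(role, []):
                col = normed.get(alias)
                if col is not None and col not in claimed:
                    out[role] = col
                    claimed.add(col)
                    break
        return out


DEFAULT_HEADER_MAP = HeaderMap(
    {
        "element_id": [
            "data element id", "element id", "de id", "de name",
            "de short label", "short label", "variable name", "variable id",
            "variable", "var name", "field name", "element name", "name", "id",
        ],
        "description": [
            "data element description", "element description",
            "de description", "variable label", "variable description",
            "description", "label", "desc", "question",
        ],
        "data_type": ["data type", "type", "datatype", "field type", "format"],
        "length": ["length", "len", "field length", "width", "size"],
        "group_id": [
            "group id", "group id (= form name)", "group", "group name",
            "form id", "form name", "form", "crf", "crf name", "table",
            "table name", "dataset", "domain",
        ],
        "form_title": [
            "title", "form title", "form name", "form description",
            "description", "label", "name",
        ],
        "pv_element_id": [
            "data element id", "element id", "de id", "variable name",
            "variable id", "variable", "element",
        ],
        "pv_value_id": [
            "permissible value id", "value id", "pv id", "code",
            "coded value", "short label",
        ],
        "pv_value": ["permissible value", "value", "pv", "response"],
        "pv_description": [
            "permissible value description", "value description",
            "value label", "description", "label", "meaning", "decode",
        ],
    }
)


def _read_csv(path: Path | str, sniff: bool = True) -> Optional[pd.DataFrame]:
    """Read a CSV as strings; None for an empty file.

    UTF-8 BOM tolerated; with ``sniff`` the delimiter (comma / tab /
    semicolon) is detected, matching the variety of platform exports.
    """
    path = Path(path)
    if path.suffix.lower() == ".pdf":
        raise UnsupportedFormatError(
            f"{path.name}: PDF dictionaries are not machine-readable here; "
            "convert to CSV first",
            code="pdf_dictionary",
        )
    kwargs: dict = dict(dtype=str, keep_default_na=False, encoding="utf-8-sig")
    import csv as _csv

    try:
        if sniff:
            try:
                df = pd.read_csv(path, sep=None, engine="python", **kwargs)
            except _csv.Error:  # sniffing fails on trivial/one-column files
                df = pd.read_csv(path, **kwargs)
        else:
            df = pd.read_csv(path, **kwargs)
    except pd.errors.EmptyDataError:
        logger.warning("empty dictionary file %s", path)
        return None
    return df


def _clean(token: str, missing_tokens: frozenset[str]) -> Optional[str]:
    token = (token or "").strip()
    if token.casefold() in missing_tokens:
        return None
    return token


def _parse_length(token: Optional[str]) -> Optional[int]:
    if token is None:
        return None
    try:
        n = int(float(token))
    except ValueError:
        return None
    return n if n >= 1 else None


def read_element_dictionary(
    files: Sequence[Path | str] | Path | str,
    study_id: str,
    header_map: Optional[HeaderMap] = None,
    synonyms: Optional[dict] = None,
    missing_tokens: frozenset[str] = DEFAULT_MISSING_TOKENS,
    positional_fallback: bool = False,
    sniff: bool = True,
) -> list[DataElement]:
    """Parse one element dictionary, possibly split across several CSV files.

    Rows from multiple files are concatenated in the given order; duplicate
    element IDs (case-insensitive) are deduplicated keeping the first
    occurrence, with a logged count.  When no element-ID header resolves the
    file is rejected unless ``positional_fallback`` is set, in which case
    column 1 is taken as the ID and column 2 as the description.
    """
    if isinstance(files, (str, Path)):
        files = [files]
    if not files:
        raise UnreadableDictionaryError("no element dictionary files given")
    hmap = header_map or DEFAULT_HEADER_MAP
    elements: list[DataElement] = []
    seen: dict[str, int] = {}
    n_dupes = 0
    for f in files:
        df = _read_csv(f, sniff=sniff)
        if df is None:
            continue
        roles = hmap.resolve(df.columns, ["element_id", "description", "data_type", "length", "group_id"])
        if "element_id" not in roles:
            if positional_fallback and df.shape[1] >= 1:
                roles["element_id"] = df.columns[0]
                if df.shape[1] >= 2 and "description" not in roles:
                    roles["description"] = df.columns[1]
                logger.warning("positional header fallback used for %s", f)
            else:
                raise UnreadableDictionaryError(
                    f"{f}: no element-ID column recognized "
                    f"(headers: {list(df.columns)})",
                    file=str(f),
                )
        for _, row in df.iterrows():
            eid = _clean(row[roles["element_id"]], missing_tokens)
            if eid is None:
                continue
            key = normalize_token(eid)
            if key in seen:
                n_dupes += 1
                continue
            raw_type = (
                _clean(row[roles["data_type"]], missing_tokens)
                if "data_type" in roles else None
            )
            elem = DataElement(
                study_id=study_id,
                element_id=eid,
                description=(
                    _clean(row[roles["description"]], missing_tokens) or ""
                    if "description" in roles else ""
                ),
                raw_type=raw_type,
                data_type=normalize_data_type(raw_type, synonyms),
                length=_parse_length(
                    _clean(row[roles["length"]], missing_tokens)
                    if "length" in roles else None
                ),
                group_id=(
                    _clean(row[roles["group_id"]], missing_tokens)
                    if "group_id" in roles else None
                ),
            )
            seen[key] = 1
            elements.append(elem)
    if n_dupes:
        logger.warning(
            "study %s: %d duplicate element IDs dropped (first kept)",
            study_id, n_dupes,
        )
    return elements


def read_forms_dictionary(
    file: Path | str,
    study_id: str,
    header_map: Optional[HeaderMap] = None,
    missing_tokens: frozenset[str] = DEFAULT_MISSING_TOKENS,
    sniff: bool = True,
) -> list[FormEntry]:
    """Parse a forms dictionary CSV: one entry per row, order preserved."""
    hmap = header_map or DEFAULT_HEADER_MAP
    df = _read_csv(file, sniff=sniff)
    if df is None:
        return []
    roles = hmap.resolve(df.columns, ["group_id", "form_title"])
    if "group_id" not in roles:
        raise UnreadableDictionaryError(
            f"{file}: no group-ID column recognized (headers: {list(df.columns)})",
            file=str(file),
        )
    if "form_title" not in roles:
        logger.warning("%s: no form-title column; titles left empty", file)
    forms: list[FormEntry] = []
    for _, row in df.iterrows():
        gid = _clean(row[roles["group_id"]], missing_tokens)
        if gid is None:
            logger.warning("%s: row without group ID skipped", file)
            continue
        title = (
            _clean(row[roles["form_title"]], missing_tokens) or ""
            if "form_title" in roles else ""
        )
        forms.append(FormEntry(study_id=study_id, group_id=gid, title=title))
    return forms


def read_pv_dictionary(
    file: Path | str,
    study_id: str,
    header_map: Optional[HeaderMap] = None,
    missing_tokens: frozenset[str] = DEFAULT_MISSING_TOKENS,
    sniff: bool = True,
) -> list[PermissibleValue]:
    """Parse a permissible-value dictionary CSV.

    The value-ID column is optional; element-ID and at least one of
    value / description are required.  (study, element, value) duplicates
    are dropped keeping the first.
    """
    hmap = header_map or DEFAULT_HEADER_MAP
    df = _read_csv(file, sniff=sniff)
    if df is None:
        return []
    roles = hmap.resolve(
        df.columns, ["pv_element_id", "pv_value_id", "pv_value", "pv_description"]
    )
    if "pv_element_id" not in roles:
        raise UnreadableDictionaryError(
            f"{file}: no element-ID column recognized (headers: {list(df.columns)})",
            file=str(file),
        )
    if "pv_value" not in roles and "pv_description" not in roles:
        raise UnreadableDictionaryError(
            f"{file}: neither a value nor a description column recognized",
            file=str(file),
        )
    pvs: list[PermissibleValue] = []
    seen: set[tuple[str, str]] = set()
    for _, row in df.iterrows():
        eid = _clean(row[roles["pv_element_id"]], missing_tokens)
        if eid is None:
            continue
        value = (
            _clean(row[roles["pv_value"]], missing_tokens)
            if "pv_value" in roles else None
        )
        desc = (
            _clean(row[roles["pv_description"]], missing_tokens)
            if "pv_description" in roles else None
        )
        if value is None and desc is None:
            logger.warning("%s: permissible value row with no content skipped", file)
            continue
        key = (normalize_token(eid), (value or "").strip())
        if key in seen:
            logger.warning("%s: duplicate permissible value %s dropped", file, key)
            continue
        seen.add(key)
        pvs.append(
            PermissibleValue(
                study_id=study_id,
                element_id=eid,
                value=value or "",
                value_id=(
                    _clean(row[roles["pv_value_id"]], missing_tokens)
                    if "pv_value_id" in roles else None
                ),
                description=desc,
            )
        )
    return pvs


_AGG_COLUMNS = [
    "study_id", "element_id", "description", "data_type",
    "raw_type", "length", "group_id", "flags",
]


def write_aggregate_elements(elements: Iterable[DataElement], path: Path | str) -> None:
    """Write the aggregate data-elements file (stable column order).

    Round-trips losslessly through :func:`read_aggregate_elements`; flags are
    serialized as semicolon-joined tokens, empty string when none.
    """
    rows = [
        {
            "study_id": e.study_id,
            "element_id": e.element_id,
            "description": e.description,
            "data_type": e.data_type.value,
            "raw_type": e.raw_type or "",
            "length": "" if e.length is None else str(e.length),
            "group_id": e.group_id or "",
            "flags": flags_to_str(e.flags),
        }
        for e in elements
    ]
    if not rows:
        raise ValueError("refusing to write an empty aggregate elements file")
    pd.DataFrame(rows, columns=_AGG_COLUMNS).to_csv(
        path, index=False, lineterminator="\n"
    )


def read_aggregate_elements(path: Path | str) -> list[DataElement]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8-sig")
    out = []
    for _, row in df.iterrows():
        out.append(
            DataElement(
                study_id=row["study_id"],
                element_id=row["element_id"],
                description=row["description"],
                raw_type=row["raw_type"] or None,
                data_type=DataType(row["data_type"]),
                length=int(row["length"]) if row["length"] else None,
                group_id=row["group_id"] or None,
                flags=flags_from_str(row["flags"]),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Packaged worked-example fixtures (element, forms, and PV dictionaries).

def fixture_path(name: str) -> Path:
    p = resources.files("dictqc") / "data" / name
    return Path(str(p))


def load_example_elements(study_id: str = "NCT00099359") -> list[DataElement]:
    """Ten element rows from a neonatal antiretroviral trial's dictionary."""
    return read_element_dictionary([fixture_path("example_elements.csv")], study_id)


def load_example_forms(study_id: str = "NCT01751646") -> list[FormEntry]:
    """Six forms (of 40) from a vitamin-D absorption study, including two
    distinct forms that share the title 'Specimen Tracking Form'."""
    return read_forms_dictionary(fixture_path("example_forms.csv"), study_id)


def load_example_pvs(study_id: str = "NCT01772823") -> list[PermissibleValue]:
    """The six permissible values of OFFTXR (reason for discontinuation)."""
    return read_pv_dictionary(fixture_path("example_pvs.csv"), study_id)
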