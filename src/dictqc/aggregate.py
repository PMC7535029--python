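"""Cross-study aggregation of dictionaries.

Combines per-study element dictionaries into a data-type distribution
(percentages over *typed* elements only), harmonizes form names via a
user-supplied synonym map and tabulates common forms (a form is *very
common* when present in at least half of the studies that supplied a forms
dictionary, inclusive), and aggregates permissible-value statistics (mean
values per categorical element, share of numeric-coded value sets, most
frequent value descriptions).

Form-name harmonization is map-driven only: no automatic edit-distance
clustering is attempted (mapping synonymous titles is a curation task), and
no semantic matching of identical elements across studies is performed.
"""

from __future__ import annotations

import logging
import statistics
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import yaml

from .ipd import is_numeric_token
from .model import (
    DataType,
    FormEntry,
    PermissibleValue,
    StudyDictionary,
    normalize_text,
    normalize_token,
    percent,
    round_ratio,
)

logger = logging.getLogger(__name__)

__all__ = [
    "AggregateStats",
    "TypeShare",
    "CommonForm",
    "PVStats",
    "SynonymMap",
    "ConfigurationError",
    "aggregate_elements",
    "harmonize_form_names",
    "common_forms",
    "aggregate_pv_stats",
    "near_duplicate_titles",
]


class ConfigurationError(ValueError):
    """Conflicting synonym-map entries."""


@dataclass
class TypeShare:
    count: int
    pct_of_typed: float


@dataclass
class CommonForm:
    name: str
    n_studies: int
    pct_of_studies: float
    very_common: bool


@dataclass
class PVStats:
    n_pvs_total: int
    n_elements_with_pvs: int
    mean_pvs_per_element: float
    n_numeric_coded: int
    pct_numeric_coded: float
    top_value_descriptions: list[tuple[str, int, int]]  # (desc, n elements, n studies)


@dataclass
class AggregateStats:
    n_studies: int
    n_elements_total: int
    per_study_counts: dict[str, int]
    median_elements: float
    min_elements: int
    max_elements: int
    n_untyped: int
    type_distribution: dict[str, TypeShare]
    common_forms: list[CommonForm] = field(default_factory=list)
    pv_stats: Optional[PVStats] = None


@dataclass
class SynonymMap:
    """Raw form title or group ID → preferred harmonized name.

    ``global_map`` applies everywhere; ``per_study`` entries (keyed by study
    ID) take precedence.  Unmapped titles pass through lower-cased (with
    whitespace collapsed).  Keys are compared case-insensitively; two
    entries for the same key with different preferred names are a
    configuration error.
    """

    global_map: dict[str, str] = field(default_factory=dict)
    per_study: dict[str, dict[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.global_map = self._normalize(self.global_map)
        self.per_study = {
            study: self._normalize(m) for study, m in self.per_study.items()
        }

    @staticmethod
    def _normalize(mapping: Mapping[str, str]) -> dict[str, str]:
        out: dict[str, str] = {}
        for raw, preferred in mapping.items():
            key = normalize_text(raw)
            preferred = normalize_text(preferred)
            if key in out and out[key] != preferred:
                raise ConfigurationError(
                    f"conflicting synonym entries for {raw!r}: "
                    f"{out[key]!r} vs {preferred!r}"
                )
            out[key] = preferred
        return out

    @classmethod
    def from_yaml(cls, path) -> "SynonymMap":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls(
            global_map=data.get("global", {}),
            per_study=data.get("per_study", {}),
        )

    def lookup(self, form: FormEntry) -> str:
        for mapping in (self.per_study.get(form.study_id, {}), self.global_map):
            for key in (normalize_text(form.title), normalize_text(form.group_id)):
                if key and key in mapping:
                    return mapping[key]
        # pass-through normalization
        return normalize_text(form.title) or normalize_text(form.group_id)


def harmonize_form_names(
    forms: Sequence[FormEntry], synonym_map: Optional[SynonymMap] = None
) -> list[FormEntry]:
    """Set ``harmonized_name`` on every form entry (in place; returns list)."""
    smap = synonym_map or SynonymMap()
    for f in forms:
        f.harmonized_name = smap.lookup(f)
    return list(forms)


def aggregate_elements(studies: Sequence[StudyDictionary]) -> AggregateStats:
    """Element-level cross-study totals and the data-type distribution.

    Type percentages are computed over typed elements only (elements with an
    unknown type are reported separately), so the shares answer "of the
    elements that declare a type, how many are strings?".
    """
    if not studies:
        raise ValueError("at least one study is required")
    per_study = {s.study_id: len(s.elements) for s in studies}
    all_elements = [e for s in studies for e in s.elements]
    n_total = len(all_elements)
    n_untyped = sum(1 for e in all_elements if e.data_type is DataType.UNKNOWN)
    n_typed = n_total - n_untyped
    type_distribution: dict[str, TypeShare] = {}
    for dtype in (DataType.STRING, DataType.NUMERIC, DataType.DATE,
                  DataType.DATETIME, DataType.CATEGORICAL):
        count = sum(1 for e in all_elements if e.data_type is dtype)
        if count == 0 and dtype is DataType.CATEGORICAL:
            continue  # no observed study declares categorical
        type_distribution[dtype.value] = TypeShare(
            count=count,
            pct_of_typed=percent(count, n_typed, 1) if n_typed else 0.0,
        )
    counts = list(per_study.values())
    return AggregateStats(
        n_studies=len(studies),
        n_elements_total=n_total,
        per_study_counts=per_study,
        median_elements=statistics.median(counts) if counts else 0.0,
        min_elements=min(counts) if counts else 0,
        max_elements=max(counts) if counts else 0,
        n_untyped=n_untyped,
        type_distribution=type_distribution,
    )


def common_forms(
    studies: Sequence[StudyDictionary],
    very_common_threshold: float = 0.5,
    synonym_map: Optional[SynonymMap] = None,
) -> list[CommonForm]:
    """Harmonized form names present in >= 2 studies, with study counts.

    Percentages are over studies that supplied a forms dictionary; the
    ``very_common`` flag is inclusive at the threshold (a form in exactly
    half of the studies is very common at the default 0.5).  Output is
    sorted by study count descending, then name ascending, and is invariant
    to study ordering.
    """
    if not (0 < very_common_threshold <= 1):
        raise ValueError("very_common_threshold must be in (0, 1]")
    with_forms = [s for s in studies if s.forms]
    if len(with_forms) < 2:
        logger.warning(
            "common-form analysis needs >= 2 studies with forms dictionaries "
            "(got %d)", len(with_forms)
        )
        return []
    smap = synonym_map or SynonymMap()
    name_studies: dict[str, set[str]] = {}
    for s in with_forms:
        for f in s.forms:
            name = f.harmonized_name or smap.lookup(f)
            if name:
                name_studies.setdefault(name, set()).add(s.study_id)
    n_sf = len(with_forms)
    rows = [
        CommonForm(
            name=name,
            n_studies=len(ids),
            pct_of_studies=percent(len(ids), n_sf, 1),
            very_common=len(ids) / n_sf >= very_common_threshold,
        )
        for name, ids in name_studies.items()
        if len(ids) >= 2
    ]
    rows.sort(key=lambda r: (-r.n_studies, r.name))
    return rows


def near_duplicate_titles(forms: Sequence[FormEntry]) -> list[list[str]]:
    """Groups of distinct raw titles that collapse to the same normalized
    text (case/whitespace-insensitive) — an aid for synonym-map curation."""
    groups: dict[str, set[str]] = {}
    for f in forms:
        key = normalize_text(f.title)
        if key:
            groups.setdefault(key, set()).add(f.title.strip())
    return [sorted(v) for v in groups.values() if len(v) >= 2]


def aggregate_pv_stats(
    studies: Sequence[StudyDictionary], top_n: int = 10
) -> Optional[PVStats]:
    """Permissible-value statistics across studies.

    An element is *numeric-coded* when every one of its permissible values
    parses as a number.  Top value descriptions are ranked by the number of
    distinct (study, element) pairs using them.  Returns None (with a
    warning) when no study has permissible values.
    """
    by_owner: dict[tuple[str, str], list[PermissibleValue]] = {}
    for s in studies:
        for pv in s.permissible_values:
            by_owner.setdefault((s.study_id, pv.element_key), []).append(pv)
    if not by_owner:
        logger.warning("no permissible values found in any study")
        return None
    n_pvs = sum(len(v) for v in by_owner.values())
    n_owners = len(by_owner)
    n_numeric = sum(
        1
        for pvs in by_owner.values()
        if all(
            is_numeric_token(pv.value, leading_zero_is_string=False)
            for pv in pvs
            if pv.value
        )
        and any(pv.value for pv in pvs)
    )
    desc_owners: dict[str, set[tuple[str, str]]] = {}
    desc_spelling: dict[str, str] = {}
    for owner, pvs in by_owner.items():
        for pv in pvs:
            key = normalize_text(pv.description)
            if not key:
                continue
            desc_spelling.setdefault(key, pv.description.strip())
            desc_owners.setdefault(key, set()).add(owner)
    top = sorted(
        (
            (desc_spelling[k], len(owners), len({study for study, _ in owners}))
            for k, owners in desc_owners.items()
        ),
        key=lambda t: (-t[1], t[0]),
    )[:top_n]
    return PVStats(
        n_pvs_total=n_pvs,
        n_elements_with_pvs=n_owners,
        mean_pvs_per_element=round_ratio(n_pvs, n_owners, 2),
        n_numeric_coded=n_numeric,
        pct_numeric_coded=percent(n_numeric, n_owners, 1),
        top_value_descriptions=top,
    )
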