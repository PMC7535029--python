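"""Machine checks for the CONSIDER data-sharing recommendations.

The CONSIDER statement (Consolidated Recommendations for Sharing Individual
Participant Data from Human Clinical Studies) enumerates best practices for
sharing study data and dictionaries.  Seven recommendations are scored here
against a parsed study package:

C1  Provide the data dictionary separate from the de-identified IPD.
C2  Share the dictionary as soon as possible (process — not machine-evaluable).
C3  Provide the dictionary in a single, machine-readable file.
C4  Provide a data type for every data element.
C5  For categorical elements, provide permissible values and distinguish
    codes from literal values.
C6  Provide a complete dictionary (all data elements covered, all applicable
    dictionary kinds present, descriptions populated).
C7  Adopt previously defined common data elements at design time
    (process — not machine-evaluable).

C2 and C7 are reported as ``not_evaluable`` rather than dropped, so the
checklist always carries exactly seven records.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

from .ipd import IPDTable, profile_tables
from .model import DataType, SourceFormat, StudyDictionary
from .quality import (
    DEFAULT_MAX_DISTINCT,
    dictionary_completeness,
    flag_categorical_candidates,
)

__all__ = ["CheckStatus", "ConsiderCheck", "ConsiderResult", "evaluate_consider"]


class CheckStatus(str, Enum):
    PASS = "pass"
    FAIL = "fail"
    NOT_EVALUABLE = "not_evaluable"

    def __str__(self) -> str:
        return self.value


@dataclass
class ConsiderCheck:
    check_id: str
    status: CheckStatus
    evidence: str


@dataclass
class ConsiderResult:
    study_id: str
    checks: list[ConsiderCheck]
    counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.checks) != 7:
            raise ValueError("a CONSIDER result must have exactly 7 checks")
        self.counts = {
            status.value: sum(1 for c in self.checks if c.status is status)
            for status in CheckStatus
        }

    def status_of(self, check_id: str) -> CheckStatus:
        return next(c.status for c in self.checks if c.check_id == check_id)


def evaluate_consider(
    dictionary: StudyDictionary,
    ipd: Optional[Sequence[IPDTable]] = None,
    max_distinct: int = DEFAULT_MAX_DISTINCT,
) -> ConsiderResult:
    """Score a parsed study package against the seven recommendations.

    "Machine-readable" is operationalized as: the dictionary parsed without
    positional header guessing (an unparseable package shows up here as
    failed checks with the parse problem as evidence).  Statuses are
    deterministic given the package, and adding a missing artifact can only
    move a check from fail toward pass.
    """
    checks: list[ConsiderCheck] = []

    # C1 — dictionary exists as its own artifact, not inferred from the IPD.
    if dictionary.elements and dictionary.source_format is not SourceFormat.INFERRED_FROM_IPD:
        checks.append(ConsiderCheck(
            "C1", CheckStatus.PASS,
            f"element dictionary provided separately "
            f"({len(dictionary.elements)} elements, "
            f"format {dictionary.source_format})",
        ))
    elif dictionary.elements:
        checks.append(ConsiderCheck(
            "C1", CheckStatus.FAIL,
            "no dictionary artifact was shared; it had to be inferred from IPD",
        ))
    else:
        checks.append(ConsiderCheck(
            "C1", CheckStatus.FAIL, "no element dictionary could be parsed",
        ))

    checks.append(ConsiderCheck(
        "C2", CheckStatus.NOT_EVALUABLE,
        "timing of dictionary sharing is a process property not visible "
        "in the shared package",
    ))

    # C3 — single machine-readable file.
    if (
        dictionary.source_format is SourceFormat.CSV_SINGLE
        and dictionary.n_source_files == 1
    ):
        checks.append(ConsiderCheck(
            "C3", CheckStatus.PASS, "single CSV dictionary file",
        ))
    else:
        checks.append(ConsiderCheck(
            "C3", CheckStatus.FAIL,
            f"{dictionary.n_source_files} files "
            f"(format {dictionary.source_format})",
        ))

    # C4 — every element carries a data type.
    n_untyped = sum(
        1 for e in dictionary.elements if e.data_type is DataType.UNKNOWN
    )
    if dictionary.elements and n_untyped == 0:
        checks.append(ConsiderCheck(
            "C4", CheckStatus.PASS, "every element declares a data type",
        ))
    else:
        checks.append(ConsiderCheck(
            "C4", CheckStatus.FAIL,
            f"{n_untyped} of {len(dictionary.elements)} elements lack a data type",
        ))

    # C5 — categorical elements have PVs with distinguishable codes.
    profiles = profile_tables(ipd) if ipd else None
    flags = flag_categorical_candidates(
        dictionary.elements,
        dictionary.permissible_values,
        profiles=profiles,
        max_distinct=max_distinct,
    )
    pvs_by_elem = dictionary.pvs_by_element()
    bad: list[str] = []
    for fl in flags:
        linked = pvs_by_elem.get(fl.element_id.strip().casefold(), [])
        if not linked:
            bad.append(f"{fl.element_id} (no permissible values)")
        elif not all(pv.value_id or pv.description for pv in linked):
            bad.append(f"{fl.element_id} (codes not distinguishable)")
    if not flags:
        checks.append(ConsiderCheck(
            "C5", CheckStatus.PASS, "no categorical candidates detected",
        ))
    elif not bad:
        checks.append(ConsiderCheck(
            "C5", CheckStatus.PASS,
            f"all {len(flags)} categorical candidates carry permissible "
            "values with codes distinguishable from literals",
        ))
    else:
        checks.append(ConsiderCheck(
            "C5", CheckStatus.FAIL,
            "categorical elements without usable permissible values: "
            + ", ".join(sorted(bad)[:20]),
        ))

    # C6 — complete dictionary, all applicable kinds, descriptions populated.
    if ipd:
        completeness = dictionary_completeness(ipd, dictionary)
        problems: list[str] = []
        if completeness.pct_in_dictionary < 100.0:
            problems.append(
                f"completeness {completeness.pct_in_dictionary}%; missing: "
                + ", ".join(sorted(completeness.missing_element_ids)[:20])
            )
        if not dictionary.forms:
            problems.append("no forms dictionary")
        if flags and not dictionary.permissible_values:
            # PV dictionary is applicable only when categorical elements exist
            problems.append("categorical elements but no permissible-value dictionary")
        n_nodesc = sum(1 for e in dictionary.elements if not e.has_description)
        if n_nodesc:
            problems.append(f"{n_nodesc} elements without description")
        if problems:
            checks.append(ConsiderCheck("C6", CheckStatus.FAIL, "; ".join(problems)))
        else:
            checks.append(ConsiderCheck(
                "C6", CheckStatus.PASS,
                "dictionary covers all data columns; applicable dictionary "
                "kinds present; descriptions populated",
            ))
    else:
        checks.append(ConsiderCheck(
            "C6", CheckStatus.NOT_EVALUABLE,
            "completeness requires IPD, which was not supplied",
        ))

    checks.append(ConsiderCheck(
        "C7", CheckStatus.NOT_EVALUABLE,
        "common-data-element adoption happens at study design time and is "
        "not visible in the shared package",
    ))

    return ConsiderResult(study_id=dictionary.study_id, checks=checks)
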