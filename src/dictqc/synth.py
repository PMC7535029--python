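"""Seeded synthetic study packages with known injected defects.

The generator emulates the empirical structure of shared clinical-study
packages: per-study element counts spanning two orders of magnitude
(log-uniform over 46–9,945, median near a few hundred), a data-type mix of
roughly 48.6% string / 47.8% numeric / 3.0% date / 0.6% date-time among
typed elements, 2–124 forms per study, and permissible-value sets averaging
about 4.23 values per categorical element with about 83% of sets using
numeric codes.

Every package comes with a :class:`GroundTruth` roster, and defects
(missing types or descriptions, elements present in data but absent from
the dictionary, categorical elements stripped of their value sets,
duplicated form titles, dictionaries split across files) are injected in
exactly known numbers — the oracle for every recovery test downstream.

Generation is fully deterministic per (spec, seed): the same inputs yield
byte-identical packages on disk.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io import read_element_dictionary, read_forms_dictionary, read_pv_dictionary
from .ipd import IPDTable, read_ipd_dir
from .model import (
    FLAG_DESCRIPTION_IDENTICAL,
    DataElement,
    DataType,
    FormEntry,
    PermissibleValue,
    SourceFormat,
    StudyDictionary,
)

__all__ = [
    "CohortSpec",
    "DefectSpec",
    "GroundTruth",
    "StudyPackage",
    "InfeasibleDefectError",
    "generate_study",
    "inject_defects",
    "generate_cohort",
    "write_package",
    "read_package",
    "FORM_VOCABULARY",
]

_RAW_TOKEN = {
    DataType.STRING: "CHAR",
    DataType.NUMERIC: "NUMBER",
    DataType.DATE: "DATE",
    DataType.DATETIME: "DATETIME",
}

_WORDS = (
    "visit date blood pressure weight height dose drug result test sample "
    "status score event grade site count cell plasma serum urine screen "
    "baseline week month therapy response reason history symptom pain fever "
    "rash nausea infection viral load antibody titer specimen collection "
    "subject age education income smoking alcohol adherence severity onset "
    "duration outcome followup clinic nurse chart review entry record"
).split()

_PV_DESCRIPTIONS = (
    "No", "Yes", "Mild", "Moderate", "Severe", "Other", "Not Applicable",
    "Refused", "Don't Know", "Missing", "Normal", "Abnormal", "Positive",
    "Negative", "Completed", "Discontinued",
)

#: Case-report-form titles shared across studies (the common-form signal).
FORM_VOCABULARY = (
    "Off Study", "Eligibility", "Visit Report", "Adverse Event", "Diagnoses",
    "Demographics", "Concomitant Medications", "Laboratory Results",
    "Physical Exam", "Medical History", "Specimen Tracking", "Vital Signs",
    "Pregnancy Test", "Follow Up", "End of Study", "Body Measurements",
    "Family History", "Missed Visit", "Behavior", "Skin Test", "Enrollment",
    "Randomization", "Protocol Deviations", "Questionnaire",
    "Informed Consent", "Substance Use", "Quality of Life",
    "Neurocognitive Assessment", "Immunization Record", "Telephone Contact",
)


class InfeasibleDefectError(ValueError):
    """More defects requested than eligible targets exist."""

    def __init__(self, kind: str, requested: int, available: int):
        super().__init__(
            f"defect {kind!r}: requested {requested} but only {available} "
            "eligible targets"
        )
        self.kind = kind
        self.requested = requested
        self.available = available


@dataclass
class CohortSpec:
    """Study-generation conditions.

    Defaults are the observed cohort structure: element counts log-uniform
    over [46, 9945]; type mix 0.486/0.478/0.030/0.006; forms uniform over
    [2, 124]; categorical fraction 0.15 of string/numeric elements;
    permissible values per categorical element min 2, mean 4.23; 83.3% of
    value sets numeric-coded.  ``n_ipd_rows = 0`` skips IPD generation.
    """

    n_studies: int = 18
    element_count_range: tuple[int, int] = (46, 9945)
    type_mix: dict[str, float] = field(
        default_factory=lambda: {
            "string": 0.486, "numeric": 0.478, "date": 0.030, "datetime": 0.006,
        }
    )
    forms_range: tuple[int, int] = (2, 124)
    frac_categorical: float = 0.15
    pv_mean: float = 4.23
    pv_min: int = 2
    frac_pv_numeric_coded: float = 0.833
    n_ipd_rows: int = 30
    missing_rate: float = 0.02
    #: harmonized form name -> number of studies it must appear in;
    #: None lets :func:`generate_cohort` build a default plan.
    common_form_counts: Optional[dict[str, int]] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.type_mix.values()) - 1.0) > 1e-9:
            raise ValueError("type_mix must sum to 1")
        if self.n_studies < 1:
            raise ValueError("n_studies must be >= 1")
        lo, hi = self.element_count_range
        if not (1 <= lo <= hi):
            raise ValueError("invalid element_count_range")
        flo, fhi = self.forms_range
        if not (1 <= flo <= fhi):
            raise ValueError("invalid forms_range")
        if self.pv_min < 1 or self.pv_mean < self.pv_min:
            raise ValueError("pv_mean must be >= pv_min >= 1")
        if not (0 <= self.frac_categorical <= 1):
            raise ValueError("frac_categorical must be in [0, 1]")


@dataclass
class DefectSpec:
    """Counts (int) or fractions of the eligible population (float < 1)
    per defect kind.  Element-level defects are applied disjointly: no
    element receives two defects."""

    drop_type: int | float | None = None
    drop_description: int | float | None = None
    set_description_equal_to_name: int | float | None = None
    omit_from_dictionary: int | float | None = None
    miscode_categorical_as_plain: int | float | None = None
    duplicate_form_title: int | float | None = None
    split_dictionary_into_k_files: int | None = None


@dataclass
class GroundTruth:
    """True schema and injected-defect roster for one synthetic study."""

    study_id: str
    schema: dict[str, dict]  # element_id -> {type, group, categorical, pv_values}
    defects: dict[str, list[str]] = field(default_factory=dict)

    def defect_count(self, kind: str) -> int:
        return len(self.defects.get(kind, []))


@dataclass
class StudyPackage:
    """A synthetic study: dictionaries plus IPD tables."""

    study_id: str
    dictionary: StudyDictionary
    ipd: list[IPDTable] = field(default_factory=list)
    n_dict_files: int = 1


def _rng_for(spec_seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([spec_seed, *key]))


def _unique_ids(rng: np.random.Generator, n: int) -> list[str]:
    alphabet = np.array(list("ABCDEFGHIJKLMNOPQRSTUVWXYZ"))
    ids: list[str] = []
    seen: set[str] = set()
    while len(ids) < n:
        need = n - len(ids)
        block = rng.choice(alphabet, size=(need + 8, 6))
        for row in block:
            token = "".join(row)
            if token not in seen:
                seen.add(token)
                ids.append(token)
                if len(ids) == n:
                    break
    return ids


def _description(rng: np.random.Generator) -> str:
    k = int(rng.integers(2, 6))
    words = rng.choice(_WORDS, size=k, replace=True)
    text = " ".join(words)
    return text[0].upper() + text[1:]


def _random_date(rng: np.random.Generator) -> str:
    y = int(rng.integers(1990, 2021))
    m = int(rng.integers(1, 13))
    d = int(rng.integers(1, 29))
    return f"{y:04d}-{m:02d}-{d:02d}"


def _random_datetime(rng: np.random.Generator) -> str:
    return (
        f"{_random_date(rng)}T{int(rng.integers(0, 24)):02d}:"
        f"{int(rng.integers(0, 60)):02d}:{int(rng.integers(0, 60)):02d}"
    )


def _proper_value(rng: np.random.Generator, dtype: str) -> str:
    if dtype == "string":
        # two words plus a number: free-text-like, effectively never repeats
        a, b = rng.choice(_WORDS, size=2, replace=True)
        return f"{a} {b} {int(rng.integers(0, 1000))}"
    if dtype == "numeric":
        if rng.random() < 0.3:
            return str(round(float(rng.uniform(0, 1000)), 2))
        return str(int(rng.integers(1, 1_000_000_000)))
    if dtype == "date":
        return _random_date(rng)
    return _random_datetime(rng)


def _make_pv_set(
    rng: np.random.Generator,
    spec: CohortSpec,
    study_id: str,
    element_id: str,
    numeric_coded: bool,
) -> list[PermissibleValue]:
    k = spec.pv_min + int(rng.poisson(spec.pv_mean - spec.pv_min))
    if numeric_coded:
        values = [str(i + 1) for i in range(k)]
        if k > 2 and rng.random() < 0.3:
            values[-1] = "99"
    else:
        pool = rng.permutation(_WORDS)
        values = [str(pool[i % len(pool)]) for i in range(k)]
    if k == 2:
        descriptions = ["No", "Yes"]
    else:
        descriptions = list(
            rng.choice(_PV_DESCRIPTIONS, size=k, replace=k > len(_PV_DESCRIPTIONS))
        )
        # "No" is the single most frequent value description in real
        # aggregates; bias larger sets toward containing it
        if "No" not in descriptions and rng.random() < 0.4:
            descriptions[0] = "No"
    return [
        PermissibleValue(
            study_id=study_id,
            element_id=element_id,
            value=values[i],
            value_id=str(i + 1),
            description=descriptions[i],
        )
        for i in range(k)
    ]


def generate_study(
    spec: CohortSpec,
    study_index: int = 0,
    title_pool: Optional[Sequence[str]] = None,
) -> tuple[StudyPackage, GroundTruth]:
    """Generate one defect-free synthetic study package with ground truth.

    The dictionary is complete and consistent with the IPD by construction:
    every IPD column is defined, every element is typed and described, and
    categorical columns draw only from their permissible-value set.
    """
    rng = _rng_for(spec.seed, 1, study_index)
    study_id = f"NCT9{study_index:07d}"
    lo, hi = spec.element_count_range
    n_elements = int(round(math.exp(rng.uniform(math.log(lo), math.log(hi)))))
    n_elements = max(lo, min(hi, n_elements))
    flo, fhi = spec.forms_range
    n_forms = int(rng.integers(flo, fhi + 1))
    n_forms = min(n_forms, n_elements)

    pool = list(title_pool) if title_pool is not None else list(FORM_VOCABULARY)
    titles = list(rng.permutation(pool))
    while len(titles) < n_forms:
        # filler titles are study-specific so they never collide across
        # studies in the common-form analysis
        titles.append(f"Study {study_index} Form {len(titles) + 1}")
    group_ids = [f"F{i + 1}" for i in range(n_forms)]
    forms = [
        FormEntry(study_id=study_id, group_id=g, title=t)
        for g, t in zip(group_ids, titles[:n_forms])
    ]

    element_ids = _unique_ids(rng, n_elements)
    type_names = list(spec.type_mix)
    probs = np.array([spec.type_mix[t] for t in type_names])
    types = [str(t) for t in rng.choice(type_names, size=n_elements, p=probs)]
    # every form gets at least one element; the rest are assigned at random
    groups = [group_ids[i] for i in range(n_forms)] + [
        str(g) for g in rng.choice(group_ids, size=n_elements - n_forms)
    ]

    # categorical elements: drawn from the numeric- vs string-typed pools at
    # the numeric-coded share, so declared types stay consistent with data
    numeric_idx = [i for i, t in enumerate(types) if t == "numeric"]
    string_idx = [i for i, t in enumerate(types) if t == "string"]
    n_cat = int(round(spec.frac_categorical * (len(numeric_idx) + len(string_idx))))
    n_cat_numeric = min(int(round(spec.frac_pv_numeric_coded * n_cat)), len(numeric_idx))
    n_cat_string = min(n_cat - n_cat_numeric, len(string_idx))
    cat_numeric = (
        set(rng.choice(numeric_idx, size=n_cat_numeric, replace=False).tolist())
        if n_cat_numeric else set()
    )
    cat_string = (
        set(rng.choice(string_idx, size=n_cat_string, replace=False).tolist())
        if n_cat_string else set()
    )

    elements: list[DataElement] = []
    pvs: list[PermissibleValue] = []
    schema: dict[str, dict] = {}
    pv_values_by_idx: dict[int, list[str]] = {}
    for i, (eid, dtype, gid) in enumerate(zip(element_ids, types, groups)):
        categorical = i in cat_numeric or i in cat_string
        if categorical:
            pv_set = _make_pv_set(rng, spec, study_id, eid, i in cat_numeric)
            pvs.extend(pv_set)
            pv_values_by_idx[i] = [pv.value for pv in pv_set]
        length = {
            "string": int(rng.integers(2, 80)),
            "numeric": int(rng.integers(1, 12)),
            "date": 10,
            "datetime": 19,
        }[dtype]
        elements.append(
            DataElement(
                study_id=study_id,
                element_id=eid,
                description=_description(rng),
                raw_type=_RAW_TOKEN[DataType(dtype)],
                data_type=DataType(dtype),
                length=length,
                group_id=gid,
            )
        )
        schema[eid] = {
            "type": dtype,
            "group": gid,
            "categorical": categorical,
            "pv_values": pv_values_by_idx.get(i),
        }

    ipd: list[IPDTable] = []
    if spec.n_ipd_rows > 0:
        by_group: dict[str, list[int]] = {}
        for i, gid in enumerate(groups):
            by_group.setdefault(gid, []).append(i)
        for gid in group_ids:
            cols = by_group.get(gid, [])
            if not cols:
                continue
            values: dict[str, list[str]] = {}
            for i in cols:
                dtype = types[i]
                if i in pv_values_by_idx:
                    col = [
                        str(v) for v in rng.choice(
                            pv_values_by_idx[i], size=spec.n_ipd_rows
                        )
                    ]
                else:
                    col = [
                        _proper_value(rng, dtype) for _ in range(spec.n_ipd_rows)
                    ]
                if spec.missing_rate > 0:
                    mask = rng.random(spec.n_ipd_rows) < spec.missing_rate
                    col = ["" if m else v for v, m in zip(col, mask)]
                    if all(v == "" for v in col):
                        col[0] = _proper_value(rng, dtype)
                values[element_ids[i]] = col
            ipd.append(
                IPDTable(
                    table_name=gid,
                    column_ids=[element_ids[i] for i in cols],
                    values=values,
                )
            )

    dictionary = StudyDictionary(
        study_id=study_id,
        elements=elements,
        forms=forms,
        permissible_values=pvs,
        source_format=SourceFormat.CSV_SINGLE,
        n_source_files=1,
    )
    package = StudyPackage(study_id=study_id, dictionary=dictionary, ipd=ipd)
    truth = GroundTruth(study_id=study_id, schema=schema)
    return package, truth


def _resolve_count(value: int | float | None, population: int, kind: str) -> int:
    if value is None:
        return 0
    if isinstance(value, float) and 0 <= value < 1:
        return int(round(value * population))
    count = int(value)
    if count < 0:
        raise ValueError(f"defect {kind!r}: negative count")
    return count


def inject_defects(
    package: StudyPackage,
    truth: GroundTruth,
    defects: DefectSpec,
    seed: int = 0,
) -> tuple[StudyPackage, GroundTruth]:
    """Apply a defect specification to a copy of a package.

    Targets are sampled uniformly without replacement from the eligible
    population of each defect kind; element-level defect kinds never share a
    target.  The updated ground-truth roster records exactly which elements
    or forms were touched.  Infeasible counts raise
    :class:`InfeasibleDefectError` naming the limiting population.
    """
    pkg = copy.deepcopy(package)
    tr = copy.deepcopy(truth)
    rng = _rng_for(seed, 2)
    d = pkg.dictionary
    used: set[str] = set()

    def sample(eligible: list[str], want: int | float | None, kind: str) -> list[str]:
        pool = [e for e in eligible if e not in used]
        count = _resolve_count(want, len(pool), kind)
        if count > len(pool):
            raise InfeasibleDefectError(kind, count, len(pool))
        if count == 0:
            return []
        chosen = [str(x) for x in rng.choice(pool, size=count, replace=False)]
        used.update(chosen)
        return chosen

    by_id = {e.element_id: e for e in d.elements}
    cat_ids = [
        e.element_id for e in d.elements if truth.schema[e.element_id]["categorical"]
    ]

    # miscode first: it must target categorical elements, the scarcest pool
    chosen = sample(cat_ids, defects.miscode_categorical_as_plain,
                    "miscode_categorical_as_plain")
    if chosen:
        drop = set(chosen)
        d.permissible_values = [
            pv for pv in d.permissible_values if pv.element_id not in drop
        ]
        tr.defects["miscode_categorical_as_plain"] = sorted(chosen)

    chosen = sample(
        [e.element_id for e in d.elements if e.data_type is not DataType.UNKNOWN],
        defects.drop_type, "drop_type",
    )
    for eid in chosen:
        by_id[eid].raw_type = None
        by_id[eid].data_type = DataType.UNKNOWN
    if chosen:
        tr.defects["drop_type"] = sorted(chosen)

    chosen = sample(
        [e.element_id for e in d.elements if e.has_description],
        defects.drop_description, "drop_description",
    )
    for eid in chosen:
        by_id[eid].description = ""
    if chosen:
        tr.defects["drop_description"] = sorted(chosen)

    chosen = sample(
        [
            e.element_id for e in d.elements
            if FLAG_DESCRIPTION_IDENTICAL not in e.flags
        ],
        defects.set_description_equal_to_name, "set_description_equal_to_name",
    )
    for eid in chosen:
        by_id[eid].description = eid
        by_id[eid].flags.add(FLAG_DESCRIPTION_IDENTICAL)
    if chosen:
        tr.defects["set_description_equal_to_name"] = sorted(chosen)

    chosen = sample(
        [e.element_id for e in d.elements],
        defects.omit_from_dictionary, "omit_from_dictionary",
    )
    if chosen:
        gone = set(chosen)
        d.elements = [e for e in d.elements if e.element_id not in gone]
        d.permissible_values = [
            pv for pv in d.permissible_values if pv.element_id not in gone
        ]
        tr.defects["omit_from_dictionary"] = sorted(chosen)

    n_dupes = _resolve_count(
        defects.duplicate_form_title, len(d.forms) // 2, "duplicate_form_title"
    )
    if n_dupes:
        if 2 * n_dupes > len(d.forms):
            raise InfeasibleDefectError(
                "duplicate_form_title", n_dupes, len(d.forms) // 2
            )
        idx = [int(i) for i in rng.choice(len(d.forms), size=2 * n_dupes, replace=False)]
        touched = []
        for j in range(n_dupes):
            src, dst = d.forms[idx[2 * j]], d.forms[idx[2 * j + 1]]
            dst.title = src.title
            touched.append(src.title)
        tr.defects["duplicate_form_title"] = sorted(touched)

    if defects.split_dictionary_into_k_files:
        k = int(defects.split_dictionary_into_k_files)
        if k > len(d.elements):
            raise InfeasibleDefectError(
                "split_dictionary_into_k_files", k, len(d.elements)
            )
        pkg.n_dict_files = k
        d.n_source_files = k
        if k > 1:
            d.source_format = SourceFormat.CSV_MULTI
        tr.defects["split_dictionary_into_k_files"] = [str(k)]

    return pkg, tr


def generate_cohort(
    spec: CohortSpec,
) -> list[tuple[StudyPackage, GroundTruth]]:
    """Generate ``spec.n_studies`` independent studies from per-study seeds.

    A shared common-form vocabulary is planted so the cross-study form
    analysis has signal: each planned form name is appended (under a fresh
    group ID) to exactly the requested number of studies.  Per-study random
    form titles are drawn from outside the planned names, so planted counts
    are exact.
    """
    rng = _rng_for(spec.seed, 3)
    plan = spec.common_form_counts
    if plan is None:
        k = min(8, len(FORM_VOCABULARY))
        plan = {}
        for name in FORM_VOCABULARY[:k]:
            if spec.n_studies >= 2:
                plan[name] = int(rng.integers(2, spec.n_studies + 1))
    for name, count in plan.items():
        if count > spec.n_studies:
            raise ValueError(
                f"common form {name!r} requested in {count} studies but the "
                f"cohort has {spec.n_studies}"
            )
    planned = {n.casefold() for n in plan}
    pool = [t for t in FORM_VOCABULARY if t.casefold() not in planned]
    cohort = [
        generate_study(spec, i, title_pool=pool) for i in range(spec.n_studies)
    ]
    for name, count in plan.items():
        chosen = rng.choice(spec.n_studies, size=count, replace=False)
        for j in sorted(int(c) for c in chosen):
            pkg, _ = cohort[j]
            gid = f"CF{len(pkg.dictionary.forms) + 1}"
            pkg.dictionary.forms.append(
                FormEntry(study_id=pkg.study_id, group_id=gid, title=name)
            )
    return cohort


# ---------------------------------------------------------------------------
# Disk round trip

_ELEM_HEADERS = [
    "Data Element ID", "Data Element Description", "Data Type",
    "Length", "Group ID",
]


def write_package(package: StudyPackage, outdir: Path | str) -> list[Path]:
    """Write a package as plain CSV files (deterministic bytes).

    Layout: ``elements.csv`` (or ``elements_part01.csv`` ... when the split
    defect is active), ``forms.csv``, ``pvs.csv`` and one ``ipd/<table>.csv``
    per data table.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    d = package.dictionary
    rows = [
        {
            "Data Element ID": e.element_id,
            "Data Element Description": e.description,
            "Data Type": e.raw_type or "",
            "Length": "" if e.length is None else str(e.length),
            "Group ID": e.group_id or "",
        }
        for e in d.elements
    ]
    k = max(1, package.n_dict_files)
    chunks = np.array_split(np.arange(len(rows)), k) if rows else [np.array([], int)]
    for part, idx in enumerate(chunks):
        name = "elements.csv" if k == 1 else f"elements_part{part + 1:02d}.csv"
        path = outdir / name
        pd.DataFrame(
            [rows[i] for i in idx], columns=_ELEM_HEADERS
        ).to_csv(path, index=False, lineterminator="\n")
        written.append(path)
    forms_path = outdir / "forms.csv"
    pd.DataFrame(
        [{"Group ID": f.group_id, "Description": f.title} for f in d.forms],
        columns=["Group ID", "Description"],
    ).to_csv(forms_path, index=False, lineterminator="\n")
    written.append(forms_path)
    pvs_path = outdir / "pvs.csv"
    pd.DataFrame(
        [
            {
                "Permissible Value ID": pv.value_id or "",
                "Permissible Value": pv.value,
                "Permissible Value Description": pv.description or "",
                "Data Element ID": pv.element_id,
            }
            for pv in d.permissible_values
        ],
        columns=[
            "Permissible Value ID", "Permissible Value",
            "Permissible Value Description", "Data Element ID",
        ],
    ).to_csv(pvs_path, index=False, lineterminator="\n")
    written.append(pvs_path)
    if package.ipd:
        ipd_dir = outdir / "ipd"
        ipd_dir.mkdir(exist_ok=True)
        for table in package.ipd:
            path = ipd_dir / f"{table.table_name}.csv"
            pd.DataFrame(
                {c: table.values[c] for c in table.column_ids}
            ).to_csv(path, index=False, lineterminator="\n")
            written.append(path)
    return written


def read_package(directory: Path | str, study_id: str) -> StudyPackage:
    """Read back a package written by :func:`write_package`."""
    directory = Path(directory)
    elem_files = sorted(directory.glob("elements*.csv"))
    elements = read_element_dictionary(elem_files, study_id)
    forms_path = directory / "forms.csv"
    forms = (
        read_forms_dictionary(forms_path, study_id) if forms_path.exists() else []
    )
    pvs_path = directory / "pvs.csv"
    pvs = read_pv_dictionary(pvs_path, study_id) if pvs_path.exists() else []
    ipd = read_ipd_dir(directory / "ipd") if (directory / "ipd").is_dir() else []
    dictionary = StudyDictionary(
        study_id=study_id,
        elements=elements,
        forms=forms,
        permissible_values=pvs,
        source_format=(
            SourceFormat.CSV_SINGLE if len(elem_files) == 1 else SourceFormat.CSV_MULTI
        ),
        n_source_files=len(elem_files),
    )
    return StudyPackage(
        study_id=study_id,
        dictionary=dictionary,
        ipd=ipd,
        n_dict_files=len(elem_files),
    )
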