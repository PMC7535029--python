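"""Cross-study aggregation: type distribution, forms, permissible values."""

import pytest

from dictqc.aggregate import (
    ConfigurationError,
    SynonymMap,
    aggregate_elements,
    aggregate_pv_stats,
    common_forms,
    harmonize_form_names,
    near_duplicate_titles,
)
from dictqc.model import (
    DataElement,
    FormEntry,
    PermissibleValue,
    StudyDictionary,
)
from dictqc.synth import CohortSpec, generate_cohort


def _study_with_types(study, counts):
    """counts: {raw_type_token_or_None: n}"""
    elements = []
    i = 0
    for raw, n in counts.items():
        for _ in range(n):
            elements.append(
                DataElement(study_id=study, element_id=f"{study}E{i}", raw_type=raw)
            )
            i += 1
    return StudyDictionary(study_id=study, elements=elements)


def test_type_distribution_over_typed_elements():
    # scaled-down version of the aggregate type table: same shares, small n
    study = _study_with_types(
        "S1", {"CHAR": 486, "NUMBER": 478, "DATE": 30, "DATETIME": 6, None: 100}
    )
    stats = aggregate_elements([study])
    assert stats.n_elements_total == 1100
    assert stats.n_untyped == 100
    dist = stats.type_distribution
    assert dist["string"].count == 486
    assert dist["string"].pct_of_typed == 48.6
    assert dist["numeric"].pct_of_typed == 47.8
    assert dist["date"].pct_of_typed == 3.0
    assert dist["datetime"].pct_of_typed == 0.6
    assert sum(s.count for s in dist.values()) == stats.n_elements_total - stats.n_untyped


def test_single_typed_element_is_100_percent():
    stats = aggregate_elements([_study_with_types("S", {"CHAR": 1})])
    assert stats.type_distribution["string"].pct_of_typed == 100.0


def test_totals_are_conserved_across_studies():
    studies = [
        _study_with_types("A", {"CHAR": 5, None: 2}),
        _study_with_types("B", {"NUMBER": 3}),
    ]
    stats = aggregate_elements(studies)
    assert stats.n_elements_total == sum(len(s.elements) for s in studies)
    assert stats.per_study_counts == {"A": 7, "B": 3}
    assert stats.min_elements == 3 and stats.max_elements == 7


def test_harmonize_with_synonym_map():
    smap = SynonymMap(per_study={
        "NCTA": {"F89": "family history"},
        "NCTB": {"hxw0100": "family history"},
    })
    forms = [
        FormEntry(study_id="NCTA", group_id="F89", title="F89"),
        FormEntry(study_id="NCTB", group_id="hxw0100", title="hxw0100"),
        FormEntry(study_id="NCTA", group_id="G1", title="Adverse Event"),
    ]
    harmonize_form_names(forms, smap)
    assert forms[0].harmonized_name == "family history"
    assert forms[1].harmonized_name == "family history"
    assert forms[2].harmonized_name == "adverse event"  # pass-through, lowered


def test_empty_map_passes_everything_through():
    forms = [FormEntry(study_id="S", group_id="G", title="  Off   Study ")]
    harmonize_form_names(forms)
    assert forms[0].harmonized_name == "off study"


def test_conflicting_synonym_entries_rejected():
    with pytest.raises(ConfigurationError):
        SynonymMap(global_map={"F89": "family history", "f89": "medical history"})


def _cohort_dicts(n_studies, name_counts, seed=11):
    spec = CohortSpec(
        n_studies=n_studies,
        element_count_range=(20, 40),
        forms_range=(2, 5),
        n_ipd_rows=0,
        common_form_counts=name_counts,
        seed=seed,
    )
    return [pkg.dictionary for pkg, _ in generate_cohort(spec)]


def test_common_forms_counts_and_inclusive_threshold():
    dicts = _cohort_dicts(
        18, {"Off Study": 11, "Adverse Event": 9, "Family History": 2}
    )
    table = common_forms(dicts, 0.5)
    by_name = {r.name: r for r in table}
    off = by_name["off study"]
    assert (off.n_studies, off.pct_of_studies, off.very_common) == (11, 61.1, True)
    ae = by_name["adverse event"]
    assert (ae.pct_of_studies, ae.very_common) == (50.0, True)  # boundary inclusive
    fh = by_name["family history"]
    assert (fh.n_studies, fh.very_common) == (2, False)


def test_common_forms_requires_two_studies():
    dicts = _cohort_dicts(1, {})
    assert common_forms(dicts) == []


def test_common_forms_invariant_to_study_order():
    dicts = _cohort_dicts(6, {"Off Study": 4})
    assert common_forms(dicts) == common_forms(list(reversed(dicts)))


def test_raising_threshold_never_adds_very_common():
    dicts = _cohort_dicts(10, {"Off Study": 7, "Diagnoses": 4})
    flags_low = {r.name: r.very_common for r in common_forms(dicts, 0.3)}
    flags_high = {r.name: r.very_common for r in common_forms(dicts, 0.6)}
    for name, high in flags_high.items():
        assert not (high and not flags_low[name])


def test_near_duplicate_titles_reported():
    forms = [
        FormEntry(study_id="S", group_id="A", title="Off Study"),
        FormEntry(study_id="S", group_id="B", title="OFF  STUDY"),
    ]
    assert near_duplicate_titles(forms) == [["OFF  STUDY", "Off Study"]]


def _pv_study(study, n_elements, pvs_per_element, numeric_frac=1.0):
    pvs = []
    n_numeric = round(numeric_frac * n_elements)
    for i in range(n_elements):
        numeric = i < n_numeric
        for j in range(pvs_per_element[i % len(pvs_per_element)]):
            pvs.append(
                PermissibleValue(
                    study_id=study,
                    element_id=f"{study}E{i}",
                    value=str(j + 1) if numeric else f"level {j}",
                    description="No" if j == 0 else f"desc {j}",
                )
            )
    return StudyDictionary(study_id=study, permissible_values=pvs)


def test_pv_mean_and_numeric_coding():
    # 100 elements, 60 with 4 values and 40 with 5 -> mean 4.40; 83 numeric
    pvs_per = [4] * 3 + [5] * 2  # cycle gives 60/40 split over 100
    study = _pv_study("S", 100, pvs_per, numeric_frac=0.83)
    stats = aggregate_pv_stats([study])
    assert stats.n_elements_with_pvs == 100
    assert stats.n_pvs_total == 60 * 4 + 40 * 5
    assert stats.mean_pvs_per_element == 4.40
    assert stats.n_numeric_coded == 83
    assert stats.pct_numeric_coded == 83.0
    # every element contributes one "No" description
    top_desc, n_pairs, n_studies = stats.top_value_descriptions[0]
    assert top_desc == "No" and n_pairs == 100 and n_studies == 1


def test_single_element_mean():
    from dictqc.io import load_example_pvs

    sd = StudyDictionary(study_id="S", permissible_values=load_example_pvs("S"))
    stats = aggregate_pv_stats([sd])
    assert stats.n_pvs_total == 6
    assert stats.mean_pvs_per_element == 6.00
    assert stats.pct_numeric_coded == 100.0  # 1,2,3,4,5,99 are all numbers


def test_no_pvs_anywhere_returns_none():
    assert aggregate_pv_stats([StudyDictionary(study_id="S")]) is None


def test_pv_mean_matches_brute_force_on_synthetic_cohort():
    spec = CohortSpec(
        n_studies=4, element_count_range=(50, 150), forms_range=(2, 6),
        n_ipd_rows=0, seed=99,
    )
    dicts = [pkg.dictionary for pkg, _ in generate_cohort(spec)]
    stats = aggregate_pv_stats(dicts)
    flat = [pv for d in dicts for pv in d.permissible_values]
    owners = {(pv.study_id, pv.element_key) for pv in flat}
    from dictqc.model import round_ratio

    assert stats.n_pvs_total == len(flat)
    assert stats.n_elements_with_pvs == len(owners)
    assert stats.mean_pvs_per_element == round_ratio(len(flat), len(owners), 2)
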