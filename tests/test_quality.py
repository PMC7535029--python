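"""Per-study quality metrics."""

import pytest

from dictqc.ipd import IPDTable, profile_column
from dictqc.model import (
    FLAG_NUMERIC_CATEGORICAL,
    FLAG_STRING_CATEGORICAL,
    DataElement,
    DataType,
    FormEntry,
    PermissibleValue,
    StudyDictionary,
    UndefinedRatioError,
)
from dictqc.quality import (
    assess_study,
    description_stats,
    detect_duplicate_form_titles,
    dictionary_completeness,
    flag_categorical_candidates,
    missing_type_stats,
)
from dictqc.synth import CohortSpec, DefectSpec, generate_study, inject_defects


def _ipd_of(ids):
    return [IPDTable("T", list(ids), {c: ["1"] for c in ids})]


class TestCompleteness:
    def test_partial_dictionary(self):
        ids = [f"C{i}" for i in range(389)]
        sd = StudyDictionary(
            study_id="S",
            elements=[DataElement(study_id="S", element_id=c) for c in ids[:337]],
        )
        res = dictionary_completeness(_ipd_of(ids), sd)
        assert (res.n_elements_in_data, res.n_in_dictionary) == (389, 337)
        assert res.pct_in_dictionary == 86.6
        assert sorted(res.missing_element_ids) == sorted(ids[337:])

    def test_dictionary_superset_of_data(self):
        ids = [f"C{i}" for i in range(179)]
        sd = StudyDictionary(
            study_id="S",
            elements=[
                DataElement(study_id="S", element_id=c) for c in ids + ["EXTRA"]
            ],
        )
        res = dictionary_completeness(_ipd_of(ids), sd)
        assert res.pct_in_dictionary == 100.0
        assert res.missing_element_ids == []

    def test_matching_is_case_insensitive(self):
        sd = StudyDictionary(
            study_id="S",
            elements=[DataElement(study_id="S", element_id=" age ")],
        )
        res = dictionary_completeness(_ipd_of(["AGE"]), sd)
        assert res.pct_in_dictionary == 100.0

    def test_empty_dictionary_is_a_valid_zero(self):
        res = dictionary_completeness(
            _ipd_of(["A", "B"]), StudyDictionary(study_id="S")
        )
        assert res.n_in_dictionary == 0
        assert res.pct_in_dictionary == 0.0

    def test_monotone_under_dictionary_growth(self):
        ids = [f"C{i}" for i in range(50)]
        ipd = _ipd_of(ids)
        last = -1.0
        for k in range(0, 51, 5):
            sd = StudyDictionary(
                study_id="S",
                elements=[DataElement(study_id="S", element_id=c) for c in ids[:k]],
            )
            pct = dictionary_completeness(ipd, sd).pct_in_dictionary
            assert pct >= last
            last = pct
        assert last == 100.0


class TestTypeAndDescriptionStats:
    def test_missing_type_counts(self):
        elements = [
            DataElement(study_id="S", element_id=f"T{i}", raw_type="CHAR")
            for i in range(6)
        ] + [DataElement(study_id="S", element_id=f"U{i}") for i in range(4)]
        n, pct = missing_type_stats(elements)
        assert (n, pct) == (4, 40.0)

    def test_all_typed(self):
        elements = [
            DataElement(study_id="S", element_id=f"T{i}", raw_type="NUMBER")
            for i in range(3)
        ]
        assert missing_type_stats(elements) == (0, 0.0)

    def test_empty_input_is_undefined(self):
        with pytest.raises(UndefinedRatioError):
            missing_type_stats([])
        with pytest.raises(UndefinedRatioError):
            description_stats([])

    def test_description_stats(self):
        elements = [
            DataElement(study_id="S", element_id="A1", description="Age in years"),
            DataElement(study_id="S", element_id="A2", description=""),
            DataElement(study_id="S", element_id="DAGE", description="DAGE"),
            DataElement(study_id="S", element_id="B2", description="  dage "),
        ]
        n_missing, pct_missing, n_identical = description_stats(elements)
        assert n_missing == 1
        assert pct_missing == 25.0
        assert n_identical == 1  # only the exact normalized match counts


class TestCategoricalFlagging:
    def test_small_profile_flags_string_candidate(self):
        elem = DataElement(study_id="S", element_id="GRADE", raw_type="CHAR")
        prof = profile_column(
            ["mild", "moderate", "severe", "life threatening", "death"] * 4
        )
        flags = flag_categorical_candidates([elem], [], {"grade": prof})
        assert [f.flag for f in flags] == [FLAG_STRING_CATEGORICAL]
        assert flags[0].reason == "profile_based"
        assert FLAG_STRING_CATEGORICAL in elem.flags

    def test_many_distinct_values_not_flagged(self):
        elem = DataElement(study_id="S", element_id="VTMRSP", raw_type="CHAR")
        prof = profile_column([f"reason {i}" for i in range(107)] * 2)
        assert flag_categorical_candidates([elem], [], {"vtmrsp": prof}) == []

    def test_numeric_coded_flags_numeric_candidate(self):
        elem = DataElement(study_id="S", element_id="PAINSEV", raw_type="NUMBER")
        prof = profile_column(["0", "1", "2", "3", "9"] * 6)
        flags = flag_categorical_candidates([elem], [], {"painsev": prof})
        assert [f.flag for f in flags] == [FLAG_NUMERIC_CATEGORICAL]

    def test_pv_linked_flags_regardless_of_threshold(self):
        elem = DataElement(study_id="S", element_id="OFFTXR", raw_type="CHAR")
        pvs = [
            PermissibleValue(study_id="S", element_id="OFFTXR", value=str(v))
            for v in (1, 2, 3)
        ]
        flags = flag_categorical_candidates([elem], pvs, max_distinct=1)
        assert flags[0].reason == "pv_linked"

    def test_all_unique_column_never_flagged(self):
        elem = DataElement(study_id="S", element_id="ID", raw_type="CHAR")
        prof = profile_column([f"id-{i}" for i in range(10)])
        assert flag_categorical_candidates([elem], [], {"id": prof}) == []

    def test_date_elements_never_flagged(self):
        elem = DataElement(study_id="S", element_id="VISDT", raw_type="DATE")
        pvs = [PermissibleValue(study_id="S", element_id="VISDT", value="1")]
        assert flag_categorical_candidates([elem], pvs) == []


class TestDuplicateFormTitles:
    def test_duplicate_title_two_groups(self):
        forms = [
            FormEntry(study_id="S", group_id="B100", title="Specimen Tracking Form"),
            FormEntry(study_id="S", group_id="BSCR", title="Subject Screening Log"),
            FormEntry(study_id="S", group_id="C100", title="Specimen Tracking Form"),
        ]
        dupes = detect_duplicate_form_titles(forms)
        assert dupes == [("Specimen Tracking Form", ["B100", "C100"])]

    def test_unique_titles_empty(self):
        forms = [
            FormEntry(study_id="S", group_id=g, title=t)
            for g, t in [("A", "One"), ("B", "Two")]
        ]
        assert detect_duplicate_form_titles(forms) == []

    def test_same_title_same_group_not_ambiguous(self):
        forms = [
            FormEntry(study_id="S", group_id="A", title="One"),
            FormEntry(study_id="S", group_id="A", title="one "),
        ]
        assert detect_duplicate_form_titles(forms) == []


class TestAssessStudy:
    def test_defect_free_package(self, small_package):
        pkg, _ = small_package
        report = assess_study(pkg.dictionary, ipd=pkg.ipd)
        assert report.n_missing_type == 0
        assert report.n_missing_description == 0
        assert report.n_description_identical_to_name == 0
        assert report.duplicate_form_titles == []
        assert report.completeness.pct_in_dictionary == 100.0

    def test_injected_defects_recovered_exactly(self, small_spec):
        pkg, truth = generate_study(small_spec, 1)
        defects = DefectSpec(
            drop_type=7,
            drop_description=6,
            set_description_equal_to_name=4,
            omit_from_dictionary=9,
            miscode_categorical_as_plain=3,
            duplicate_form_title=1,
        )
        pkg2, truth2 = inject_defects(pkg, truth, defects, seed=5)
        report = assess_study(pkg2.dictionary, ipd=pkg2.ipd)
        assert report.n_missing_type == truth2.defect_count("drop_type") == 7
        assert report.n_missing_description == 6
        assert report.n_description_identical_to_name == 4
        assert sorted(report.completeness.missing_element_ids) == (
            truth2.defects["omit_from_dictionary"]
        )
        assert len(report.duplicate_form_titles) == 1
        pv_keys = pkg2.dictionary.pvs_by_element()
        flagged_without_pv = sorted(
            f.element_id for f in report.categorical_flags
            if f.element_id.casefold() not in pv_keys
        )
        assert flagged_without_pv == truth2.defects["miscode_categorical_as_plain"]

    def test_small_typed_dictionary_reports_no_missing_types(self):
        from dictqc.io import load_example_elements

        sd = StudyDictionary(study_id="S", elements=load_example_elements("S"))
        report = assess_study(sd)
        assert report.n_elements == 10
        assert report.n_missing_type == 0
        assert report.completeness is None  # no IPD supplied

    def test_report_invariant_to_element_order(self, small_package):
        pkg, _ = small_package
        sd = pkg.dictionary
        rev = StudyDictionary(
            study_id=sd.study_id,
            elements=list(reversed(sd.elements)),
            forms=sd.forms,
            permissible_values=sd.permissible_values,
        )
        a = assess_study(sd, ipd=pkg.ipd)
        b = assess_study(rev, ipd=pkg.ipd)
        assert (a.n_missing_type, a.n_missing_description,
                a.n_categorical_candidates) == (
            b.n_missing_type, b.n_missing_description, b.n_categorical_candidates
        )
        assert a.completeness.pct_in_dictionary == b.completeness.pct_in_dictionary
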