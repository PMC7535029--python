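"""Synthetic study-package generator: determinism, structure, defects."""

from pathlib import Path

import pytest

from dictqc.model import DataType
from dictqc.quality import assess_study
from dictqc.synth import (
    CohortSpec,
    DefectSpec,
    InfeasibleDefectError,
    generate_cohort,
    generate_study,
    inject_defects,
    read_package,
    write_package,
)


def test_spec_validation():
    with pytest.raises(ValueError):
        CohortSpec(type_mix={"string": 0.5, "numeric": 0.4})
    with pytest.raises(ValueError):
        CohortSpec(element_count_range=(10, 5))
    with pytest.raises(ValueError):
        CohortSpec(n_studies=0)


def test_exact_counts_when_range_is_degenerate():
    spec = CohortSpec(
        element_count_range=(46, 46), forms_range=(2, 2), n_ipd_rows=4, seed=5
    )
    pkg, truth = generate_study(spec, 0)
    assert len(pkg.dictionary.elements) == 46
    assert len(pkg.dictionary.forms) == 2
    assert len(truth.schema) == 46


def test_same_seed_byte_identical(tmp_path, small_spec):
    a, b = tmp_path / "a", tmp_path / "b"
    write_package(generate_study(small_spec, 0)[0], a)
    write_package(generate_study(small_spec, 0)[0], b)
    files_a = sorted(p.relative_to(a) for p in a.rglob("*.csv"))
    files_b = sorted(p.relative_to(b) for p in b.rglob("*.csv"))
    assert files_a == files_b
    for rel in files_a:
        assert (a / rel).read_bytes() == (b / rel).read_bytes()


def test_different_seed_differs(small_spec):
    import dataclasses

    other = dataclasses.replace(small_spec, seed=small_spec.seed + 1)
    ids_a = {e.element_id for e in generate_study(small_spec, 0)[0].dictionary.elements}
    ids_b = {e.element_id for e in generate_study(other, 0)[0].dictionary.elements}
    assert ids_a != ids_b


def test_package_round_trip_through_disk(tmp_path, small_package):
    pkg, _ = small_package
    write_package(pkg, tmp_path)
    back = read_package(tmp_path, pkg.study_id)
    assert len(back.dictionary.elements) == len(pkg.dictionary.elements)
    assert len(back.dictionary.forms) == len(pkg.dictionary.forms)
    assert len(back.dictionary.permissible_values) == len(
        pkg.dictionary.permissible_values
    )
    for a, b in zip(pkg.dictionary.elements, back.dictionary.elements):
        assert a.element_id == b.element_id
        assert a.data_type is b.data_type
        assert a.length == b.length
    report = assess_study(back.dictionary, ipd=back.ipd)
    assert report.completeness.pct_in_dictionary == 100.0


def test_ground_truth_conservation(small_package):
    pkg, truth = small_package
    assert len(pkg.dictionary.elements) == len(truth.schema)
    ids = {e.element_id for e in pkg.dictionary.elements}
    assert ids == set(truth.schema)
    # categorical elements own permissible values, others own none
    pv_owners = {pv.element_id for pv in pkg.dictionary.permissible_values}
    cat = {eid for eid, m in truth.schema.items() if m["categorical"]}
    assert pv_owners == cat


def test_ipd_columns_realize_schema(small_package):
    pkg, truth = small_package
    cols = {c for t in pkg.ipd for c in t.column_ids}
    assert cols == set(truth.schema)
    for table in pkg.ipd:
        for col in table.column_ids:
            assert truth.schema[col]["group"] == table.table_name
            allowed = truth.schema[col]["pv_values"]
            if allowed:
                observed = {
                    v for v in table.values[col] if v.strip()
                }
                assert observed <= set(allowed)


def test_defect_injection_leaves_untouched_content(small_spec):
    pkg, truth = generate_study(small_spec, 2)
    pkg2, truth2 = inject_defects(
        pkg, truth, DefectSpec(drop_type=5), seed=9
    )
    # original package is unchanged (pure function on copies)
    assert all(e.data_type is not DataType.UNKNOWN for e in pkg.dictionary.elements)
    touched = set(truth2.defects["drop_type"])
    for e in pkg2.dictionary.elements:
        if e.element_id not in touched:
            assert e.data_type is not DataType.UNKNOWN


def test_defects_are_disjoint_per_element(small_spec):
    pkg, truth = generate_study(small_spec, 0)
    _, truth2 = inject_defects(
        pkg, truth,
        DefectSpec(
            drop_type=10, drop_description=10,
            set_description_equal_to_name=5, omit_from_dictionary=10,
            miscode_categorical_as_plain=2,
        ),
        seed=3,
    )
    element_kinds = [
        "drop_type", "drop_description", "set_description_equal_to_name",
        "omit_from_dictionary", "miscode_categorical_as_plain",
    ]
    all_targets = [t for k in element_kinds for t in truth2.defects.get(k, [])]
    assert len(all_targets) == len(set(all_targets)) == 37


def test_infeasible_defect_errors(small_spec):
    pkg, truth = generate_study(small_spec, 0)
    n = len(pkg.dictionary.elements)
    with pytest.raises(InfeasibleDefectError) as err:
        inject_defects(pkg, truth, DefectSpec(drop_type=n + 1), seed=0)
    assert err.value.available == n


def test_drop_type_on_everything(small_spec):
    pkg, truth = generate_study(small_spec, 0)
    n = len(pkg.dictionary.elements)
    pkg2, _ = inject_defects(pkg, truth, DefectSpec(drop_type=n), seed=0)
    report = assess_study(pkg2.dictionary)
    assert report.pct_missing_type == 100.0


def test_fractional_defect_counts(small_spec):
    pkg, truth = generate_study(small_spec, 0)
    n = len(pkg.dictionary.elements)
    _, truth2 = inject_defects(pkg, truth, DefectSpec(drop_type=0.5), seed=0)
    assert truth2.defect_count("drop_type") == round(0.5 * n)


def test_cohort_type_shares_approach_spec():
    """Over >= 10,000 typed elements the realized type mix sits within
    two points of the specified shares."""
    spec = CohortSpec(
        n_studies=4, element_count_range=(2600, 3200), forms_range=(3, 10),
        n_ipd_rows=0, seed=17,
    )
    cohort = generate_cohort(spec)
    elements = [e for pkg, _ in cohort for e in pkg.dictionary.elements]
    assert len(elements) >= 10_000
    for name, share in spec.type_mix.items():
        got = sum(1 for e in elements if e.data_type.value == name) / len(elements)
        assert abs(got - share) <= 0.02


def test_cohort_plants_common_forms_exactly():
    spec = CohortSpec(
        n_studies=6, element_count_range=(20, 40), forms_range=(2, 4),
        n_ipd_rows=0, common_form_counts={"Off Study": 4}, seed=23,
    )
    cohort = generate_cohort(spec)
    n_with = sum(
        1 for pkg, _ in cohort
        if any(f.title == "Off Study" for f in pkg.dictionary.forms)
    )
    assert n_with == 4


def test_single_study_cohort_has_no_common_forms():
    from dictqc.aggregate import common_forms

    spec = CohortSpec(
        n_studies=1, element_count_range=(20, 30), forms_range=(2, 3),
        n_ipd_rows=0, seed=1,
    )
    dicts = [pkg.dictionary for pkg, _ in generate_cohort(spec)]
    assert common_forms(dicts) == []
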