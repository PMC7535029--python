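# dictqc — quality assessment of clinical-study data dictionaries

When a completed clinical study shares its de-identified individual
participant data (IPD), the accompanying **data dictionary** is what makes
the data reusable: it lists every data element (variable) with its
description, ID, data type, length and the case report form (CRF) it was
collected on.  In practice these dictionaries arrive as heterogeneous CSV
exports — split across dozens of files, missing types or descriptions,
silently omitting variables that appear in the data, and declaring
categorical variables as plain strings or numbers with no permissible-value
list.  Each of these defects is a known source of misinterpreted secondary
analyses.

`dictqc` is a toolkit for researchers and data-sharing platforms who curate
or aggregate such study packages.  It models a study as three dictionaries —
**element**, **forms**, and **permissible-value (PV)** — and provides:

* robust CSV readers that map variant column headers onto a five-attribute
  target data-element model (description, element ID, type, length, group ID);
* inference of an element dictionary from the IPD alone (per-column
  profiling: distinct count, max length, conservative type inference);
* per-study quality metrics:
  * **completeness** = `100 · |columns in data ∩ dictionary| / |columns in data|`
    (half-up rounding to 1 decimal, the rule used for every percentage);
  * missing-type and missing-description rates; descriptions identical to
    the element name;
  * **categorical-miscoding candidates**: elements declared `string`/`numeric`
    that either link to PVs or whose IPD column shows
    `n_distinct ≤ 20` and `n_distinct < n_nonmissing`;
  * duplicated form titles (one title, ≥ 2 group IDs);
* cross-study aggregation: data-type distribution over *typed* elements,
  map-driven form-name harmonization with a common-form table
  (*very common* = present in ≥ 50% of studies with a forms dictionary,
  inclusive), and PV statistics (mean PVs per element, share of
  numeric-coded value sets, top value descriptions);
* a checklist scorer for the seven enumerated **CONSIDER**
  data-sharing recommendations (C1–C7; the two process recommendations are
  reported `not_evaluable`);
* a seeded **synthetic study-package generator** with exact defect
  injection and a ground-truth roster, so every metric has an oracle.

## Worked example

```python
from dictqc import (load_example_elements, load_example_forms,
                    load_example_pvs, StudyDictionary, assess_study)

sd = StudyDictionary(
    study_id="NCT00099359",
    elements=load_example_elements(),          # 10 elements, 6 CRF groups
    forms=load_example_forms(),                # 6 forms
    permissible_values=load_example_pvs(),     # OFFTXR: 6 values
)
report = assess_study(sd)
print(report.n_elements, report.n_missing_type, report.pct_missing_type)
print(report.duplicate_form_titles)
```

prints

```
10 0 0.0
[('Specimen Tracking Form', ['B100', 'C100'])]
```

— all ten example elements declare a type (`CHAR`/`NUMBER`/`DATE` tokens are
normalized to `string`/`numeric`/`date`), and the forms dictionary reuses
one title, "Specimen Tracking Form", for two different forms (group IDs
B100 and C100) — exactly the kind of ambiguity the duplicate-title check
reports.

A full synthetic analysis lives under `analysis/`:

```sh
python analysis/01_simulate_cohort.py      # 18 studies, defects in 9
python analysis/02_assess_quality.py       # per-study reports + recovery check
python analysis/03_aggregate_statistics.py # type mix, common forms, PV stats
python analysis/04_consider_checklist.py   # CONSIDER scores per study
```

Each script prints its findings and writes tables under `results/`
(packages themselves go to `scratch/`).  There is also a `dictqc` console
command (`parse`, `infer`, `assess`, `aggregate`, `consider`, `simulate`)
wrapping the same functions.

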