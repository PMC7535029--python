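#!/usr/bin/env python
"""Simulate a cohort of shared study packages with injected defects.

Generates 18 synthetic studies (element counts log-uniform over 46-9,945,
realistic type mix, 2-124 forms, permissible-value sets on categorical
elements), plants a shared case-report-form vocabulary, injects dictionary
defects into every odd-numbered study, and writes the packages as plain CSV
under scratch/cohort/ together with the ground-truth defect roster.

Writes results/cohort_summary.csv (one row per study).
"""

import json
from pathlib import Path

import pandas as pd

from dictqc.synth import CohortSpec, DefectSpec, generate_cohort, inject_defects, write_package

SEED = 7
OUT = Path("scratch/cohort")
RESULTS = Path("results")

DEFECTS = DefectSpec(
    drop_type=0.10,
    drop_description=0.05,
    set_description_equal_to_name=0.02,
    omit_from_dictionary=0.08,
    miscode_categorical_as_plain=0.25,
    duplicate_form_title=1,
)


def main() -> None:
    spec = CohortSpec(
        n_studies=18,
        element_count_range=(46, 2000),  # full-width lower tail, capped upper
        common_form_counts={
            "Off Study": 11, "Eligibility": 10, "Visit Report": 10,
            "Adverse Event": 9, "Diagnoses": 9,
        },
        seed=SEED,
    )
    RESULTS.mkdir(exist_ok=True)
    rows = []
    truths = {}
    for i, (pkg, truth) in enumerate(generate_cohort(spec)):
        defective = i % 2 == 1
        if defective:
            pkg, truth = inject_defects(pkg, truth, DEFECTS, seed=SEED + i)
        write_package(pkg, OUT / pkg.study_id)
        truths[pkg.study_id] = truth.defects
        rows.append({
            "study_id": pkg.study_id,
            "n_elements": len(pkg.dictionary.elements),
            "n_forms": len(pkg.dictionary.forms),
            "n_permissible_values": len(pkg.dictionary.permissible_values),
            "n_ipd_tables": len(pkg.ipd),
            "defects_injected": defective,
        })
    (OUT / "ground_truth.json").write_text(
        json.dumps(truths, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    df = pd.DataFrame(rows)
    df.to_csv(RESULTS / "cohort_summary.csv", index=False)
    print(f"wrote {len(rows)} study packages under {OUT}/")
    print(
        f"element counts: min {df.n_elements.min()}, "
        f"median {df.n_elements.median():.0f}, max {df.n_elements.max()}"
    )
    print(f"{int(df.defects_injected.sum())} studies carry injected defects")


if __name__ == "__main__":
    main()
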