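#!/usr/bin/env python
"""Cross-study aggregation over the simulated cohort.

Combines all per-study dictionaries into an aggregate element inventory and
computes the data-type distribution (over typed elements), the common-form
table with the very-common flag at the inclusive 50% threshold, and the
permissible-value statistics (mean values per categorical element, share of
numeric-coded value sets, most frequent value descriptions).

Writes results/aggregate_stats.json, results/common_forms.csv and the
(large) aggregate element file scratch/aggregate_elements.csv.
"""

import dataclasses
import json
from pathlib import Path

import pandas as pd

from dictqc.aggregate import aggregate_elements, aggregate_pv_stats, common_forms
from dictqc.io import write_aggregate_elements
from dictqc.synth import read_package

COHORT = Path("scratch/cohort")
RESULTS = Path("results")


def main() -> None:
    if not COHORT.is_dir():
        raise SystemExit("run analysis/01_simulate_cohort.py first")
    dicts = [
        read_package(p, p.name).dictionary
        for p in sorted(q for q in COHORT.iterdir() if q.is_dir())
    ]
    stats = aggregate_elements(dicts)
    forms = common_forms(dicts, very_common_threshold=0.5)
    pv = aggregate_pv_stats(dicts)

    RESULTS.mkdir(exist_ok=True)
    payload = {
        "n_studies": stats.n_studies,
        "n_elements_total": stats.n_elements_total,
        "median_elements_per_study": stats.median_elements,
        "element_count_range": [stats.min_elements, stats.max_elements],
        "n_untyped": stats.n_untyped,
        "type_distribution": {
            k: dataclasses.asdict(v) for k, v in stats.type_distribution.items()
        },
        "pv_stats": dataclasses.asdict(pv) if pv else None,
    }
    (RESULTS / "aggregate_stats.json").write_text(
        json.dumps(payload, indent=2) + "\n", encoding="utf-8"
    )
    pd.DataFrame([dataclasses.asdict(r) for r in forms]).to_csv(
        RESULTS / "common_forms.csv", index=False
    )
    write_aggregate_elements(
        [e for d in dicts for e in d.elements],
        Path("scratch") / "aggregate_elements.csv",
    )

    print(
        f"{stats.n_elements_total} elements across {stats.n_studies} studies "
        f"(median {stats.median_elements:.0f}, "
        f"range {stats.min_elements}-{stats.max_elements}); "
        f"{stats.n_untyped} untyped"
    )
    for name, share in stats.type_distribution.items():
        print(f"  {name:9s} {share.count:6d}  {share.pct_of_typed:5.1f}% of typed")
    very = [r for r in forms if r.very_common]
    print(f"{len(forms)} common form names, {len(very)} very common (>=50%):")
    for r in very:
        print(f"  {r.name:24s} in {r.n_studies:2d} studies ({r.pct_of_studies}%)")
    if pv:
        print(
            f"{pv.n_pvs_total} permissible values over "
            f"{pv.n_elements_with_pvs} elements "
            f"(mean {pv.mean_pvs_per_element}); "
            f"{pv.pct_numeric_coded}% numeric-coded; "
            f"top description {pv.top_value_descriptions[0]!r}"
        )


if __name__ == "__main__":
    main()
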