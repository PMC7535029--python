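# Methods

## The target data-element model

A study package is modelled as three dictionaries plus optional IPD tables.

* **Element dictionary** — one row per data element with five attributes:
  description, element ID (a.k.a. DE name / short label / variable name),
  data type, length, and group ID (the CRF or data table the element
  belongs to).  Only the element ID is mandatory; every other attribute may
  be missing, and quantifying that missingness is the point of the package.
* **Forms dictionary** — group ID plus title for each CRF (or data-table
  group).  A `copyrighted` flag is carried per form; it defaults to false
  and no check sets it automatically (copyright marking is an upstream
  curation fact).
* **Permissible-value dictionary** — one row per allowed value of a
  categorical element: optional value ID (short code), the value, an
  optional description, and the owning element ID.

IDs are matched case-insensitively after whitespace stripping, everywhere
(column-to-element matching, PV linkage, duplicate detection).  This is a
declared convention, not an observed fact about any platform: exports that
differ only in case are far more often the same variable than different
ones.  It is centralised in `normalize_token` and can be tightened by
pre-processing if a corpus is known to be case-sensitive.

## Type normalization

Raw type tokens are mapped case-insensitively through a synonym table
(`char/character/string/text/varchar → string`;
`number/numeric/num/int/integer/float/decimal → numeric`; `date → date`;
`datetime/date-time/timestamp → datetime`).  Unmapped or absent tokens
become `unknown` — "missing data type" is therefore *unmappable-or-absent*,
not just absent.  The canonical `categorical` type exists in the model but
is never produced by normalization: shared dictionaries in this domain
declare categorical variables as plain strings or numbers, and the package
treats "categorical" as a quality-assessment verdict, not a parsed fact.
`enumerated`/`boolean` tokens are plausible in the wild but are not mapped
by default; the synonym table is user-extensible for corpora that use them.

## The percentage rule

Every reported percentage is `100·a/b` rounded **half-up** to one decimal
(`decimal.Decimal` arithmetic, never binary-float rounding), and means are
rounded half-up to two decimals.  Half-up rather than banker's rounding is
load-bearing: e.g. 9 945/10 755 = 92.468…% must print as 92.5 and
625/10 000 as 6.3.  A zero denominator raises `UndefinedRatioError`; no
metric silently reports 0 for an empty population.

## IPD profiling and dictionary inference

Each column is profiled in one pass: total rows, non-missing rows (missing
tokens: empty, `NA`, `N/A`, `.`), exact distinct count, maximum token
length, and an inferred type.  Inference is all-or-nothing per column:
`datetime` if every non-missing token has a recognized date + time form,
else `date`, else `numeric`, else `string`; `unknown` for all-missing
columns.  Recognized formats are a fixed list (ISO 8601, `YYYYMMDD`,
`MM/DD/YYYY`, `DD-MON-YYYY`; date-times require a time component) —
deliberately not a fuzzy parser, so that inference is deterministic and
explainable.  Numeric tokens admit sign, decimals and scientific notation,
but a leading zero followed by another digit ("007") is treated as an
ID-like string by default, to avoid typing coded identifiers as numbers.

The distinct-value *set* is retained only up to a 200-value cap (an
engineering bound); all counts stay exact regardless.

Dictionary inference emits one element per (table, column) pair with the
table name as group ID, matching how table-organized studies label their
groups.  Descriptions cannot be inferred from data and are left empty.

## Quality metrics

* **Completeness** is one-directional: the share of distinct data columns
  that the dictionary defines.  Dictionary entries absent from the data are
  reported informationally elsewhere but not penalized, since dictionaries
  legitimately describe elements not exported in a particular IPD cut.
* **Categorical candidates**: an element declared string/numeric is flagged
  if (a) it has at least one linked PV — always, the PV linkage *is* the
  evidence — or (b) its profile shows `n_distinct ≤ max_distinct` (default
  20) and `n_distinct < n_nonmissing`.  The threshold sits between the two
  canonical cases (a 5-level severity grade flags; a free-text "specify"
  field with 107 distinct responses does not); the second condition stops
  all-unique columns (IDs, measurements) from flagging at small n.
  Date/datetime elements never flag.
* **Duplicate form titles** require ≥ 2 *distinct* group IDs for one
  normalized title; repetition of a title within one group is not
  ambiguity.
* **Vague descriptions** have no operational definition in the literature;
  the package ships only a conservative heuristic (description shorter than
  3 characters, or equal to the element ID) and labels the count
  `n_vague_description_heuristic`.

## Aggregation denominators

Each cross-study statistic uses its own natural denominator, and mixing
them up changes every number: the type distribution is over *typed*
elements only; common-form percentages are over *studies with a forms
dictionary*; the numeric-coded share is over *elements with PVs*.  A form
name is *very common* when present in at least the threshold fraction of
studies (inclusive at the boundary; default 0.5).  Harmonization is
synonym-map-driven only — form-title synonymy is a curation judgement, so
the package assists (a near-duplicate-title report) but does not guess; no
cross-study semantic matching of *elements* is attempted at all.

## Synthetic study packages

The generator's defaults are the documented cohort conditions: element
counts log-uniform over [46, 9 945] (the range spans two orders of
magnitude; a log-uniform draw keeps the median in the few-hundreds without
enforcing it), type mix 0.486/0.478/0.030/0.006, forms per study uniform
over [2, 124], PV sets of size `2 + Poisson(2.23)` (mean 4.23, minimum 2),
and an 83.3% numeric-coded share.  Values chosen here because no external
statement fixes them: 15% of string/numeric elements are categorical, IPD
tables have 30 rows, and 2% of cells are missing.  Numeric-coded sets are
realized by drawing categorical elements from the numeric-typed pool (and
string-coded ones from the string pool) at the 0.833 share, so the declared
type always matches the IPD values — which is what makes exact
type-recovery testable.  Binary value sets are described "No"/"Yes" and
larger sets are biased toward containing "No", mirroring the observed
dominance of "No" among value descriptions.

Proper (non-categorical) columns are built so profile-based categorical
flagging has a negligible false-positive rate at the default row count:
string values are two words plus a number, numeric values are drawn from up
to 10⁹.  IPD realism stops at structure: token pools instead of clinical
vocabularies, no cross-column correlation, no participant-level semantics,
no informative missingness mechanism.  Passing tests therefore demonstrate metric
correctness and recovery on structurally realistic packages, not robustness
to messy real-world content (encodings, free text, inconsistent units).

Defect injection samples targets uniformly without replacement, disjointly
across element-level defect kinds, and records every target in the
ground-truth roster; infeasible counts fail before generation with the
limiting population named.  Everything is driven by
`numpy.random.default_rng` seeded from `(spec.seed, stream, study_index)`,
and a written package is byte-identical under regeneration with the same
spec.

## CONSIDER checks

C1–C7 map to artifact-level predicates where possible (C3 = exactly one
CSV source file; C4 = no unknown types; C5 = every categorical candidate
has PVs whose codes are distinguishable via value ID or description;
C6 = completeness 100.0% ∧ forms present ∧ descriptions populated ∧ a PV
dictionary *when categorical candidates exist* — a study with no
categorical elements passes C6 without one, an interpretation the result
records).  C2 (timing) and C7 (CDE adoption at design time) are process
properties and always `not_evaluable`, keeping the checklist at exactly
seven records.

## Problem sizes

Tests and the acceptance script run at desk scale by design: study
generation for metric checks uses tens-to-hundreds of elements; the
completeness scenarios use exact element counts (179–3 001); the type-mix
law-of-large-numbers check uses a cohort of ≥ 10 000 typed elements; count
fixtures (26 328 elements, 7 669 PVs) are built in memory.  The whole suite
runs in a few seconds on one CPU.

## Known limitations

* PDF and proprietary-catalog dictionaries are rejected, not parsed.
* Define-XML / SDTM / REDCap formats are acknowledged interchange targets
  but not readers.
* No terminology binding (LOINC/RxNorm) of elements or values.
* Header-alias coverage is an educated superset; unusual corpora will need
  `HeaderMap.extended`.
* The categorical-candidate threshold is a heuristic; corpora with many
  low-cardinality true-numeric measures will over-flag and should lower
  `max_distinct` or rely on PV linkage only.
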