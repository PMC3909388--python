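# cohortflow

Matched case–control cohort assembly over a coded-event EHR, with a
calibrated synthetic-data generator.

## The problem

Clinical research query tools (such as i2b2) identify study candidates from
administrative billing data: a *potential case* is any patient carrying the
right combination of diagnosis/procedure codes, and *potential controls* are
patients with the exposure codes but not the outcome code. Billing codes are
imperfect, so every candidate must then be screened by chart review against
the clinical eligibility criteria, and matched controls must be reviewed
sequentially until the target ratio is reached. The result is a
CONSORT-style attrition cascade whose arithmetic — who was excluded, why,
and at what rate — is itself a key methodological result.

`cohortflow` implements that whole loop as a tested pipeline for the
motivating study design: kidney stones among gastrostomy-tube (G-tube) fed
children. Because no patient data can ship with a package, it includes a
synthetic-EHR generator that emulates the hospital population on two layers
— a coded-event layer (what the query sees) and a latent truth layer (what a
chart reviewer finds) — calibrated so the attrition proportions default to
the published study's observed values.

## The model

* **Phenotype queries.** A case is any patient with ≥ 1 G-tube code
  (10 ICD-9 diagnosis/procedure codes ∪ 11 CPT codes) *and* ≥ 1 kidney-stone
  ICD-9 diagnosis code (592.1, 592.2, 592.9); a control candidate has a
  G-tube code and no stone code. Queries run in de-identified count mode or
  identified patient-list mode.
* **Chart review.** Cases must have an incident stone diagnosis in
  2005-01-01..2011-12-31, age 1–21 years at diagnosis, a verified G-tube
  placed before diagnosis, tube feeds in ≥ 3 of the 12 calendar months before
  diagnosis, and adequate nutrition data. Exclusion reasons are assigned in a
  fixed precedence order, one label per patient. Controls are screened
  against their matched case's index date (G-tube in place before it; the
  same 3-of-12 feed rule in the case-anchored window).
* **Matching.** Automated pool filter (same sex, date of birth ± 1 year),
  then randomized sequential review until 2 eligible controls per case or
  pool exhaustion, without replacement. With per-review eligibility *p*, the
  expected ineligible reviews per case is *r*(1 − *p*)/*p* for ratio *r*
  (negative binomial), ≈ 10.15 at the study's *p* = 0.165.
* **Generation.** Label-first: each record's screening disposition is drawn
  from a configurable probability vector (default: the study's Table-1
  proportions), then a record is constructed that provably screens as that
  label — giving an exact round-trip test and exact calibration. A
  `--fixed-margins` mode allocates labels by largest-remainder counts so the
  study's integer flow (177 → 136 → 41 cases; 486 → 406 → 80 controls) is
  reproduced deterministically.

## Worked example

```bash
cohortflow all --fixed-margins --seed 1 --outdir out
```

prints:

```
Reasons for exclusion of potential study participants
Reason for exclusion                Excluded potential cases (N = 136)    Excluded potential controls (N = 406)
---------------------------------------------------------------------------------------------------------------
Inaccurate query
  No kidney stone                   28 (20.6)                             NA
  No G-tube                         3 (2.2)                               31 (7.6)
Did not meet inclusion criteria
  Outside of study age range        42 (30.9)                             NA
  Outside of study time period      35 (25.7)                             NA
  Kidney stone/G-tube asynchronous  14 (10.3)                             82 (20.2)
Inadequate clinical data            13 (9.6)                              293 (72.2)
Other
  No matching control               1 (0.7)                               NA

Cases: 177 identified -> 136 excluded -> 41 included (23.2% of identified)
Controls: 486 reviewed -> 406 excluded -> 80 included (16.5% of reviewed)
Case exclusions from inaccurate coding: 31 (22.8%)
Control exclusions from inaccurate coding: 31 (7.6%)
Control charts reviewed per matched case (ineligible only): mean 9.9, sd 2.7 (n = 41 matched cases)
```

Reading it: the code query identified 177 potential cases, of whom 41
(23.2%) survived chart review; one otherwise-includable case was dropped
because no eligible control existed. 486 matched control charts were
reviewed to find 80 eligible controls (16.5%; two cases retained only one
control each). Exclusion percentages are per-reason fractions of the
excluded total — e.g. 72.2% of control exclusions were for inadequate
nutrition data, while cases were far more often excluded for miscoding
(22.8% vs 7.6%). Every number is also written as TSV (`flow_cases.tsv`,
`flow_controls.tsv`) alongside the per-stage artifacts (`events.tsv`,
`case_dispositions.tsv`, `matches.tsv`, `review_stats.tsv`, ...) and a JSON
manifest. Without `--fixed-margins` the same pipeline runs stochastically:
dispositions are multinomial draws and control streams are iid
per-candidate, so counts vary around the calibrated proportions.

The stages can also be run individually (`generate`, `query`, `screen`,
`match`, `report`) from each other's output files, and the whole API is
importable (`cohortflow.generate_population`, `evaluate_query`,
`assess_case`, `sequential_review`, `tabulate_flow`, ...).

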