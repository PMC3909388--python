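# Methods

## Scope and design

`cohortflow` models the assembly of a matched case–control cohort from a
coded-event clinical data repository in five stages: synthetic population
generation, boolean code-set phenotype query, chart-review screening,
sequential matched control selection, and attrition tabulation. The package
treats the *assembly process* — not the downstream risk-factor analysis — as
the object of study: its outputs are attrition counts, exclusion-reason
percentages, and review-burden statistics.

Two data layers are deliberately decoupled. The **coded-event layer**
(patient, code system, code, date) is all the query engine may see; the
**latent truth layer** (verified stone status and date, G-tube placement,
monthly feed exposure, nutrition-data adequacy) is all the screening logic
may see. Billing-code misclassification is therefore representable directly:
a record can carry a stone code while `has_true_stone` is false, which is
exactly how "inaccurate query" exclusions arise.

## The generator

Generation is **label-first and constructive**. For each potential case an
intended screening disposition is drawn from `case_disposition_probs`
(multinomial), and a record is then built that screens as exactly that label
under the criteria. The default probability vector is the observed study
attrition over 177 potential cases — included 41; no stone 28; no G-tube 3;
out-of-age 42; out-of-period 35; stone/G-tube asynchronous 14; inadequate
data 13; no matching control 1. The alternative would be a mechanistic
misclassification model (per-code sensitivity/PPV); that is out of scope
because it cannot be calibrated from the published counts alone, whereas
label-first generation guarantees calibration and yields an exact
round-trip test (generator label == screening label, 100% of records, any
seed).

Control candidates are generated as per-case lazy streams. Every candidate
matches the case on sex and date of birth within tolerance and carries
G-tube codes but no stone code (so it passes the control query); it screens
eligible with probability `control_stream_eligibility` (default 0.165, the
observed 80/486 rounded as published), otherwise its exclusion reason is
drawn from `control_ineligibility_split` (default 31 : 82 : 293 over no
G-tube / asynchronous / inadequate data). Streams end after
`control_pool_cap` candidates (default 100), modelling exhaustion of the
automated match pool; exhaustion before the ratio is met produces the
one-control and no-control outcomes seen in practice.

Quantities the source never reports were fixed once at field-plausible
values and are not tuning knobs: sex is 50/50; case index dates are uniform
over the study period; ages are uniform over the eligible range (and 0 or
22–30 years for out-of-range records); G-tube placement precedes the feed
window by 4–48 months for compliant histories; event dates are uniform over
a simulation horizon padding the study period by 5 years before and 2 after.

### Fixed-margins mode

The stochastic generator reproduces the study *proportions* in expectation.
For exact integer reproduction the pipeline offers `--fixed-margins`:

* case labels are allocated by largest-remainder counts (ties broken by
  label order), which at the default vector and n = 177 gives exactly the
  observed integers;
* control streams are planned from a `FixedControlMargins` block holding the
  observed margins — two cases short one control each, and an exact
  ineligible deck of 31 + 82 + 293 labels dealt randomly across the 41
  matchable cases. Full streams are arranged to end on the final accepted
  control so every planned ineligible chart is reviewed; short streams
  exhaust. The eligible total (80 = 39×2 + 2×1) is derived from the ratio
  and the shortfall, never stored.

This makes 486 reviewed / 406 excluded / 80 matched, and the mean of 406/41
≈ 9.9 ineligible reviews per matched case, exact identities of the
allocation rather than simulation outcomes.

## Screening rules

* **Age** is completed years with a birthday floor (a Feb-29 birthday is
  reached on Mar 1 in non-leap years); bounds are inclusive at both ends
  ([1, 21]).
* **Feed rule**: ≥ `min_months` (3) distinct calendar feed months within the
  `window_months` (12) calendar months ending at, and including, the index
  month. Calendar-month granularity was chosen because it is auditable from
  chart data; the window is anchored at the case's stone-diagnosis date for
  both the case and its controls.
* **Precedence.** A record can fail several rules but receives one label.
  The order is: stone unverifiable → G-tube unverifiable → outside study
  period → outside age range → asynchronous (stone predates placement, or
  in-window feeds < 3) → inadequate data → included. Controls: no G-tube →
  asynchronous (placement not strictly before the index date, or in-window
  feeds < 3) → inadequate data → eligible. Reported per-reason counts depend
  on this order; it follows the listing order of the criteria and matches
  the attrition-table grouping. "Incident" is operationalized as the
  (single) stone diagnosis date lying in the study period; prior-history
  patterns are generated under the asynchronous label.
* Controls are never checked for age or period directly — those rows are
  structurally "NA" for controls; temporal anchoring is inherited from the
  matched case.

## Matching

Stage one filters candidates to same-sex, |Δdob| ≤ 366 days (366 to be
conservative about "± 1 year" across leap years). Stage two shuffles the
pool (or consumes a lazy stream in generated order, which is already iid)
and screens sequentially until the ratio is met, counting ineligible
reviews. Controls are consumed without replacement by default — the
standard matched-design convention; a `replacement` flag flips it. A
consumed candidate encountered again in another case's pool is skipped
without counting as a review. Cases are processed in sorted-id order with
per-case RNG streams derived by hashing (seed, case id), so results are
independent of processing order and of how much randomness earlier cases
consumed. Included cases that end with zero controls are relabelled
"no matching control" at reporting time.

The review-burden statistic is the mean of per-case *ineligible* reviews
over matched cases; accepted controls are not counted (406/41 = 9.9
reproduces the observed statistic exactly, which resolves the ambiguity in
the prose description), and an `include_accepted` variant is provided.
Under iid eligibility p and unbounded pools the count is negative binomial
with mean r(1−p)/p ≈ 10.15 at r = 2, p = 0.165; the finite pool cap
truncates the tail negligibly (P(> 100 reviews) ≈ 2·10⁻⁶).

## Attrition tables

Percentages are recomputed from counts at render time — never stored and
re-used — as 100·n/d rounded **half-up** to 1 decimal (`decimal`-based, so
.X5 boundaries round up deterministically). Per-reason percentages use the
excluded total as denominator; headline percentages use the identified
(cases) or reviewed (controls) total. The control denominator is the number
of charts actually reviewed, not the full automated pool, matching the
published denominators (80/486). The source table prints one cell ("1
(0.73)") at 2 decimals, inconsistently with the rest; this report uses 1
decimal everywhere (0.7). Empty tables render headline percentages as NA
rather than dividing by zero.

## Numerical and determinism choices

* All randomness flows from one integer seed through named, hashed
  sub-seeds (`blake2b` of token strings, reduced below 2³¹), so every stage
  is independently re-runnable from the previous stage's files with
  identical output.
* Identical seed + configuration give byte-identical data artifacts. The
  run manifest (`manifest.json`) records wall-clock timestamps and is the
  one file excluded from that guarantee.
* Date-of-birth sampling for a target age uses rejection within the exact
  age interval, which sidesteps Feb-29 edge cases in year arithmetic.
* Largest-remainder allocation breaks remainder ties by fixed label order,
  keeping fixed-margins output seed-stable.

## Simulated problem sizes

The bundled experiments use the study's own scale: 177 potential cases;
41-case cohorts with 2:1 matching; 500 replicate cohorts for review-burden
estimates (±0.05 standard error on the mean); 10,000 records for
calibration checks (3-SE multinomial bands). These sizes make all checks
exact or tightly bounded while keeping any run to seconds.

## What the synthetic data does and does not show

The generator reproduces the *screening-outcome composition* of a real
hospital population, not its mechanisms. Passing tests demonstrate that the
query, screening, matching and accounting logic are correct and internally
consistent, and that the pipeline reproduces the published attrition
arithmetic under the published proportions. They do not validate coding
behaviour (per-code sensitivity or PPV), demographic or temporal structure
(sex is 50/50, dates uniform), correlations between exclusion reasons and
demographics, or anything about the clinical risk-factor question itself.
Two further known artifacts: candidate dates of birth are anchored to the
case (so for very young cases a synthetic control's G-tube placement can
precede its own birth — no screening rule reads that relation), and the
ineligible-review deck in fixed-margins mode spreads reviews more evenly
across cases than the observed dispersion (sd 2.7 vs the reported 8.4; the
mean is exact, the spread is not a calibration target).
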