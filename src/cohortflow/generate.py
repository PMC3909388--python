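"""Synthetic pediatric-EHR generator.

Generation is *label-first and constructive*: the screening disposition of
every potential case is sampled from a configurable probability vector
(defaulting to the observed attrition proportions), and a patient record is
then built that is guaranteed to screen as exactly that label. The coded-event
layer always carries qualifying codes regardless of the truth layer — this is
how "inaccurate query" dispositions (a stone or G-tube code without the
corresponding clinical reality) are realized.

Matched control candidates are generated as per-case lazy streams: each
candidate matches the case on sex and date of birth (within tolerance),
carries G-tube codes and no stone code, and screens eligible with the
configured per-review probability.
"""
from __future__ import annotations

import datetime
import random
from typing import Iterator, Mapping, Sequence

from ._rand import add_months, derive_seed, rand_date, rand_day_in_month
from .config import GeneratorConfig
from .phenotype import default_code_sets, gtube_code_set
from .types import (
    CASE_LABELS,
    CONTROL_EXCLUSION_ORDER,
    CONTROL_LABELS,
    CodedEvent,
    PatientRecord,
    YearMonth,
    ym_from_index,
    ym_index,
    ym_of,
)

_GTUBE_PAIRS: tuple[tuple[str, str], ...] = tuple(sorted(gtube_code_set().members))
_STONE_PAIRS: tuple[tuple[str, str], ...] = tuple(
    sorted(default_code_sets()["STONE_ICD9"].members)
)

CandidateChart = tuple[PatientRecord, list[CodedEvent]]


# ---------------------------------------------------------------------------
# low-level builders


def _events_for(
    patient_id: str,
    rng: random.Random,
    horizon,
    with_stone: bool,
) -> list[CodedEvent]:
    events = []
    for _ in range(rng.randint(1, 3)):
        system, code = rng.choice(_GTUBE_PAIRS)
        events.append(
            CodedEvent(patient_id, system, code, rand_date(rng, horizon.start, horizon.end))
        )
    if with_stone:
        for _ in range(rng.randint(1, 2)):
            system, code = rng.choice(_STONE_PAIRS)
            events.append(
                CodedEvent(
                    patient_id, system, code, rand_date(rng, horizon.start, horizon.end)
                )
            )
    return events


def _dob_for_age(rng: random.Random, on: datetime.date, age: int) -> datetime.date:
    """A date of birth such that completed age on ``on`` is exactly ``age``."""
    from ._rand import add_years
    from .review import age_at

    lo = add_years(on, -(age + 1)) + datetime.timedelta(days=1)
    hi = add_years(on, -age)
    while True:  # rejection handles Feb-29 clamping at the interval edges
        dob = rand_date(rng, lo, hi)
        if age_at(dob, on) == age:
            return dob


def _valid_gtube(
    rng: random.Random,
    anchor: datetime.date,
    dob: datetime.date,
    config: GeneratorConfig,
) -> tuple[datetime.date, frozenset[YearMonth]]:
    """G-tube placement before the feed window plus >= min_months feed months
    inside the window ending at ``anchor``'s month."""
    fr = config.feed_rule
    anchor_ym = ym_index(ym_of(anchor))
    dob_ym = ym_index(ym_of(dob))
    pm_hi = anchor_ym - fr.min_months
    pm_lo = min(pm_hi, max(dob_ym + 1, anchor_ym - 48))
    pm = rng.randint(pm_lo, pm_hi)
    placement = rand_day_in_month(rng, *ym_from_index(pm))
    window_start = anchor_ym - fr.window_months + 1
    avail = list(range(max(window_start, pm), anchor_ym + 1))
    k = rng.randint(max(fr.min_months, 1), len(avail))
    months = frozenset(ym_from_index(i) for i in rng.sample(avail, k))
    return placement, months


def _async_gtube(
    rng: random.Random,
    anchor: datetime.date,
    dob: datetime.date,
    config: GeneratorConfig,
    late_placement: bool,
) -> tuple[datetime.date, frozenset[YearMonth]]:
    """A G-tube history that violates synchrony with ``anchor``: either
    placement after the index date, or in-window feed exposure below the rule
    minimum."""
    fr = config.feed_rule
    if late_placement or fr.min_months == 0:
        placement = add_months(anchor, rng.randint(1, 24))
        pm = ym_index(ym_of(placement))
        n = rng.randint(1, 6)
        months = frozenset(
            ym_from_index(i) for i in rng.sample(range(pm, pm + 12), n)
        )
        return placement, months
    placement, _ = _valid_gtube(rng, anchor, dob, config)
    pm = ym_index(ym_of(placement))
    anchor_ym = ym_index(ym_of(anchor))
    window_start = anchor_ym - fr.window_months + 1
    avail = list(range(max(window_start, pm), anchor_ym + 1))
    j = rng.randint(0, fr.min_months - 1)
    months = frozenset(ym_from_index(i) for i in rng.sample(avail, min(j, len(avail))))
    return placement, months


# ---------------------------------------------------------------------------
# potential cases


def realize_case_disposition(
    label: str,
    config: GeneratorConfig,
    rng: random.Random,
    patient_id: str = "P00000",
) -> CandidateChart:
    """Build one potential case whose chart-review disposition is ``label``.

    The NO_CONTROL label is realized as a fully includable case (control
    availability is resolved later, in matching). Every generated case carries
    at least one G-tube code and one stone code, so all pass the case query.
    """
    if label not in CASE_LABELS:
        raise ValueError(f"unknown case disposition label {label!r}")
    period = config.study_period
    horizon = config.horizon
    lo_age, hi_age = config.age_range_years
    sex = rng.choice("MF")

    # index date (stone diagnosis) or a pseudo-anchor for stone-free records
    if label == "STUDY_PERIOD":
        before_ok = period.start > horizon.start
        after_ok = period.end < horizon.end
        if before_ok and (not after_ok or rng.random() < 0.5):
            dx = rand_date(rng, horizon.start, period.start - datetime.timedelta(days=1))
        else:
            dx = rand_date(rng, period.end + datetime.timedelta(days=1), horizon.end)
    elif label != "NO_STONE":
        dx = rand_date(rng, period.start, period.end)
    else:
        dx = None
    anchor = dx if dx is not None else rand_date(rng, period.start, period.end)

    if label == "AGE_RANGE":
        age = 0 if (lo_age > 0 and rng.random() < 0.5) else rng.randint(hi_age + 1, hi_age + 9)
    else:
        age = rng.randint(lo_age, hi_age)
    dob = _dob_for_age(rng, anchor, age)

    if label == "NO_GTUBE":
        placement: datetime.date | None = None
        feed: frozenset[YearMonth] = frozenset()
    elif label == "ASYNCHRONOUS":
        placement, feed = _async_gtube(rng, anchor, dob, config, rng.random() < 0.5)
    else:
        placement, feed = _valid_gtube(rng, anchor, dob, config)

    record = PatientRecord(
        patient_id=patient_id,
        dob=dob,
        sex=sex,
        has_true_stone=dx is not None,
        stone_dx_date=dx,
        has_true_gtube=placement is not None,
        gtube_placement_date=placement,
        feed_months=feed,
        nutrition_data_adequate=(label != "INADEQUATE_DATA"),
    )
    record.validate()
    events = _events_for(patient_id, rng, horizon, with_stone=True)
    return record, events


def largest_remainder_counts(
    probs: Mapping[str, float], n: int, label_order: Sequence[str]
) -> dict[str, int]:
    """Deterministic integer allocation of ``n`` over labels (largest
    remainder; ties broken by label order)."""
    quotas = [(lab, probs.get(lab, 0.0) * n) for lab in label_order]
    counts = {lab: int(q) for lab, q in quotas}
    short = n - sum(counts.values())
    by_frac = sorted(
        range(len(quotas)), key=lambda i: (-(quotas[i][1] - int(quotas[i][1])), i)
    )
    for i in by_frac[:short]:
        counts[quotas[i][0]] += 1
    return counts


def generate_population(
    config: GeneratorConfig, fixed_margins: bool = False
) -> tuple[list[PatientRecord], list[CodedEvent], dict[str, str]]:
    """Generate the potential-case population.

    Returns the truth-layer records, the coded-event layer, and the map
    patient_id -> intended disposition label (for round-trip verification).
    With ``fixed_margins`` the label allocation is an exact largest-remainder
    split of ``n_potential_cases`` instead of a multinomial draw.
    """
    config.validate()
    rng = random.Random(config.seed)
    n = config.n_potential_cases
    weights = [config.case_disposition_probs.get(lab, 0.0) for lab in CASE_LABELS]
    if fixed_margins:
        counts = largest_remainder_counts(config.case_disposition_probs, n, CASE_LABELS)
        labels = [lab for lab in CASE_LABELS for _ in range(counts[lab])]
        rng.shuffle(labels)
    else:
        labels = rng.choices(CASE_LABELS, weights=weights, k=n) if n else []

    records: list[PatientRecord] = []
    events: list[CodedEvent] = []
    intended: dict[str, str] = {}
    for i, label in enumerate(labels):
        pid = f"P{i:05d}"
        record, evs = realize_case_disposition(label, config, rng, pid)
        records.append(record)
        events.extend(evs)
        intended[pid] = label
    return records, events, intended


# ---------------------------------------------------------------------------
# matched control candidates


def realize_control_candidate(
    case: PatientRecord,
    label: str,
    config: GeneratorConfig,
    rng: random.Random,
    patient_id: str,
) -> CandidateChart:
    """Build one matched control candidate screening as ``label`` against the
    case's index date. Candidates always match the case on sex and date of
    birth within tolerance, and carry G-tube codes but no stone code."""
    if label not in CONTROL_LABELS:
        raise ValueError(f"unknown control disposition label {label!r}")
    index = case.stone_dx_date
    if index is None:
        raise ValueError(f"case {case.patient_id} has no index date")
    fr = config.feed_rule
    dob = case.dob + datetime.timedelta(
        days=rng.randint(-config.dob_tolerance_days, config.dob_tolerance_days)
    )

    if label == "NO_GTUBE":
        placement: datetime.date | None = None
        feed: frozenset[YearMonth] = frozenset()
    elif label == "ASYNCHRONOUS":
        placement, feed = _async_gtube(rng, index, dob, config, rng.random() < 0.5)
    else:  # ELIGIBLE or INADEQUATE_DATA: G-tube in place, feed rule satisfied
        idx_ym = ym_index(ym_of(index))
        pm_hi = idx_ym - (fr.min_months + 1)
        pm = rng.randint(min(pm_hi, idx_ym - 48), pm_hi)
        placement = rand_day_in_month(rng, *ym_from_index(pm))
        window_start = idx_ym - fr.window_months + 1
        avail = list(range(max(window_start, pm), idx_ym + 1))
        k = rng.randint(max(fr.min_months, 1), len(avail))
        feed = frozenset(ym_from_index(i) for i in rng.sample(avail, k))

    record = PatientRecord(
        patient_id=patient_id,
        dob=dob,
        sex=case.sex,
        has_true_stone=False,
        stone_dx_date=None,
        has_true_gtube=placement is not None,
        gtube_placement_date=placement,
        feed_months=feed,
        nutrition_data_adequate=(label != "INADEQUATE_DATA"),
    )
    record.validate()
    events = _events_for(patient_id, rng, config.horizon, with_stone=False)
    return record, events


def generate_control_stream(
    case: PatientRecord,
    config: GeneratorConfig,
    rng: random.Random,
    pool_cap: int | None = None,
) -> Iterator[tuple[PatientRecord, list[CodedEvent], str]]:
    """Lazy stream of matched control candidates for one case.

    Each candidate is eligible with probability
    ``config.control_stream_eligibility``; otherwise its exclusion reason is
    drawn from ``config.control_ineligibility_split``. The stream ends after
    ``pool_cap`` candidates (default ``config.control_pool_cap``), modelling
    exhaustion of the automated match pool.
    """
    if case.stone_dx_date is None:
        raise ValueError(f"case {case.patient_id} has no index date")
    cap = config.control_pool_cap if pool_cap is None else pool_cap
    split_weights = [
        config.control_ineligibility_split.get(lab, 0.0)
        for lab in CONTROL_EXCLUSION_ORDER
    ]
    for i in range(cap):
        if rng.random() < config.control_stream_eligibility:
            label = "ELIGIBLE"
        else:
            label = rng.choices(CONTROL_EXCLUSION_ORDER, weights=split_weights)[0]
        pid = f"{case.patient_id}-C{i:04d}"
        record, events = realize_control_candidate(case, label, config, rng, pid)
        yield record, events, label


def allocate_fixed_control_streams(
    case_ids: Sequence[str], config: GeneratorConfig, rng: random.Random
) -> dict[str, list[str]]:
    """Deterministic-margin control allocation: per-case candidate label
    sequences whose totals reproduce the configured fixed control margins
    exactly (eligible count derived from the match ratio and the shortfall
    pattern; ineligible reviews dealt from an exact-count deck)."""
    margins = config.fixed_control_margins
    ids = sorted(case_ids)
    if not ids:
        return {}
    n_short = min(margins.n_short_cases, len(ids))
    short = set(rng.sample(ids, n_short))
    deck = [
        lab
        for lab in CONTROL_EXCLUSION_ORDER
        for _ in range(margins.ineligible_counts.get(lab, 0))
    ]
    rng.shuffle(deck)
    buckets: dict[str, list[str]] = {cid: [] for cid in ids}
    for card in deck:
        buckets[ids[rng.randrange(len(ids))]].append(card)
    streams: dict[str, list[str]] = {}
    for cid in ids:
        n_elig = config.match_ratio - (margins.short_by if cid in short else 0)
        n_elig = max(n_elig, 0)
        seq = buckets[cid]
        if cid in short or n_elig == 0:
            # short pools exhaust: every candidate is reviewed
            seq = seq + ["ELIGIBLE"] * n_elig
            rng.shuffle(seq)
        else:
            # full pools end on the final accepted control, so every planned
            # ineligible candidate is reviewed before the stream stops
            seq = seq + ["ELIGIBLE"] * (n_elig - 1)
            rng.shuffle(seq)
            seq = seq + ["ELIGIBLE"]
        streams[cid] = seq
    return streams


def fixed_control_stream(
    case: PatientRecord,
    labels: Sequence[str],
    config: GeneratorConfig,
    rng: random.Random,
) -> Iterator[tuple[PatientRecord, list[CodedEvent], str]]:
    """Realize a planned label sequence into concrete candidate charts."""
    for i, label in enumerate(labels):
        pid = f"{case.patient_id}-C{i:04d}"
        record, events = realize_control_candidate(case, label, config, rng, pid)
        yield record, events, label


def control_rng_for_case(config: GeneratorConfig, case_id: str) -> random.Random:
    """Per-case candidate-stream RNG, independent of case iteration order."""
    return random.Random(derive_seed(config.seed, "control-stream", case_id))
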