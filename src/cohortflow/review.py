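"""Simulated chart review: deterministic screening against clinical criteria.

Screening reads only the latent truth layer of each record (the in-silico
analogue of a reviewer opening the chart) and assigns exactly one disposition
per candidate. Exclusion rules are applied in a fixed precedence order, so a
record failing several rules is counted once, under the first failing rule.
"""
from __future__ import annotations

import datetime
from typing import Iterable

from .config import EligibilityCriteria, FeedRule
from .types import Disposition, PatientRecord, YearMonth, ym_index, ym_of

#: Case exclusion rules in screening precedence order.
CASE_PRECEDENCE: tuple[str, ...] = (
    "NO_STONE",
    "NO_GTUBE",
    "STUDY_PERIOD",
    "AGE_RANGE",
    "ASYNCHRONOUS",
    "INADEQUATE_DATA",
)

CONTROL_PRECEDENCE: tuple[str, ...] = (
    "NO_GTUBE",
    "ASYNCHRONOUS",
    "INADEQUATE_DATA",
)


def age_at(dob: datetime.date, on: datetime.date) -> int:
    """Completed years of age on a date (birthday-based floor).

    A Feb-29 birthday counts as reached on Mar 1 in non-leap years.
    """
    if on < dob:
        raise ValueError(f"date {on} precedes date of birth {dob}")
    years = on.year - dob.year
    if (on.month, on.day) < (dob.month, dob.day):
        years -= 1
    return years


def feed_months_in_window(
    feed_months: Iterable[YearMonth],
    index_date: datetime.date,
    rule: FeedRule = FeedRule(),
) -> int:
    """Distinct feed months within the ``window_months`` calendar months
    ending at (and including) the month of ``index_date``."""
    end = ym_index(ym_of(index_date))
    start = end - rule.window_months + 1
    return sum(1 for m in set(feed_months) if start <= ym_index(m) <= end)


def _check_truth_fields(record: PatientRecord) -> None:
    if record.has_true_stone and record.stone_dx_date is None:
        raise ValueError(f"{record.patient_id}: stone flagged but no diagnosis date")
    if record.has_true_gtube and record.gtube_placement_date is None:
        raise ValueError(f"{record.patient_id}: G-tube flagged but no placement date")


def assess_case(record: PatientRecord, criteria: EligibilityCriteria) -> Disposition:
    """Screen a potential case.

    Rule order: stone unverifiable -> G-tube unverifiable -> diagnosis outside
    the study period -> age outside range at diagnosis -> stone/G-tube
    asynchronous (stone predates placement, or under-exposure to feeds in the
    pre-diagnosis window) -> inadequate nutrition data -> included.
    """
    _check_truth_fields(record)
    if not record.has_true_stone:
        return Disposition("NO_STONE", "case")
    if not record.has_true_gtube:
        return Disposition("NO_GTUBE", "case")
    dx = record.stone_dx_date
    assert dx is not None
    if not criteria.study_period.contains(dx):
        return Disposition("STUDY_PERIOD", "case")
    lo, hi = criteria.age_range_years
    if not lo <= age_at(record.dob, dx) <= hi:
        return Disposition("AGE_RANGE", "case")
    placement = record.gtube_placement_date
    assert placement is not None
    if dx < placement or (
        feed_months_in_window(record.feed_months, dx, criteria.feed_rule)
        < criteria.feed_rule.min_months
    ):
        return Disposition("ASYNCHRONOUS", "case")
    if not record.nutrition_data_adequate:
        return Disposition("INADEQUATE_DATA", "case")
    return Disposition("INCLUDED", "case")


def assess_control(
    record: PatientRecord,
    criteria: EligibilityCriteria,
    case_index_date: datetime.date | None,
) -> Disposition:
    """Screen a matched control candidate against its case's index date.

    Controls inherit all temporal anchoring from the case: the G-tube must be
    in place before the index date and the feed rule is evaluated in the
    case-anchored window. Age and study-period rules never apply to controls.
    """
    if case_index_date is None:
        raise ValueError(f"{record.patient_id}: matched case has no index date")
    _check_truth_fields(record)
    if not record.has_true_gtube:
        return Disposition("NO_GTUBE", "control")
    placement = record.gtube_placement_date
    assert placement is not None
    if placement >= case_index_date or (
        feed_months_in_window(record.feed_months, case_index_date, criteria.feed_rule)
        < criteria.feed_rule.min_months
    ):
        return Disposition("ASYNCHRONOUS", "control")
    if not record.nutrition_data_adequate:
        return Disposition("INADEQUATE_DATA", "control")
    return Disposition("ELIGIBLE", "control")
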