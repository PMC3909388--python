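"""Core record types shared across the pipeline.

The study population is represented on two layers that deliberately may
disagree: a *coded-event layer* (billing / procedural codes, the only thing a
code query may see) and a *latent truth layer* (what a chart reviewer would
find). Screening dispositions are assigned from the truth layer only.
"""
from __future__ import annotations

import datetime
from dataclasses import dataclass, field

#: Screening outcomes a potential case can receive (one per patient).
CASE_LABELS: tuple[str, ...] = (
    "INCLUDED",
    "NO_STONE",
    "NO_GTUBE",
    "AGE_RANGE",
    "STUDY_PERIOD",
    "ASYNCHRONOUS",
    "INADEQUATE_DATA",
    "NO_CONTROL",
)

#: Exclusion reasons in attrition-table row order for cases.
CASE_EXCLUSION_ORDER: tuple[str, ...] = (
    "NO_STONE",
    "NO_GTUBE",
    "AGE_RANGE",
    "STUDY_PERIOD",
    "ASYNCHRONOUS",
    "INADEQUATE_DATA",
    "NO_CONTROL",
)

CONTROL_LABELS: tuple[str, ...] = (
    "ELIGIBLE",
    "NO_GTUBE",
    "ASYNCHRONOUS",
    "INADEQUATE_DATA",
)

CONTROL_EXCLUSION_ORDER: tuple[str, ...] = (
    "NO_GTUBE",
    "ASYNCHRONOUS",
    "INADEQUATE_DATA",
)

#: Human-readable row titles for attrition reports.
LABEL_TITLES: dict[str, str] = {
    "INCLUDED": "Included",
    "ELIGIBLE": "Eligible",
    "NO_STONE": "No kidney stone",
    "NO_GTUBE": "No G-tube",
    "AGE_RANGE": "Outside of study age range",
    "STUDY_PERIOD": "Outside of study time period",
    "ASYNCHRONOUS": "Kidney stone/G-tube asynchronous",
    "INADEQUATE_DATA": "Inadequate clinical data",
    "NO_CONTROL": "No matching control",
}

#: Labels attributable to billing-code misclassification (true status absent
#: despite a qualifying code in the event layer).
INACCURATE_QUERY_LABELS: frozenset[str] = frozenset({"NO_STONE", "NO_GTUBE"})

VALID_CODE_SYSTEMS: frozenset[str] = frozenset({"ICD9-DX", "ICD9-PX", "CPT"})

YearMonth = tuple[int, int]


def ym_of(d: datetime.date) -> YearMonth:
    return (d.year, d.month)


def ym_index(ym: YearMonth) -> int:
    """Map a (year, month) pair to a monotone month counter."""
    y, m = ym
    if not 1 <= m <= 12:
        raise ValueError(f"month out of range: {ym!r}")
    return y * 12 + (m - 1)


def ym_from_index(i: int) -> YearMonth:
    return (i // 12, i % 12 + 1)


def format_ym(ym: YearMonth) -> str:
    return f"{ym[0]:04d}-{ym[1]:02d}"


def parse_ym(text: str) -> YearMonth:
    y, _, m = text.partition("-")
    ym = (int(y), int(m))
    ym_index(ym)  # validate
    return ym


@dataclass(frozen=True)
class CodedEvent:
    """One billing or procedural code assigned to a patient on a date."""

    patient_id: str
    code_system: str
    code: str
    date: datetime.date

    def __post_init__(self) -> None:
        if not self.code:
            raise ValueError("code must be non-empty")


@dataclass(frozen=True)
class Disposition:
    """Categorical outcome of screening one candidate chart."""

    label: str
    role: str  # "case" or "control"

    def __post_init__(self) -> None:
        if self.role == "case":
            valid = CASE_LABELS
        elif self.role == "control":
            valid = CONTROL_LABELS
        else:
            raise ValueError(f"unknown role: {self.role!r}")
        if self.label not in valid:
            raise ValueError(f"label {self.label!r} invalid for role {self.role!r}")

    @property
    def is_included(self) -> bool:
        return self.label in ("INCLUDED", "ELIGIBLE")


@dataclass
class PatientRecord:
    """Demographics plus the latent clinical-truth layer.

    ``feed_months`` holds the calendar months (year, month) during which the
    patient received tube feeds; months are only meaningful when a G-tube is
    in place.
    """

    patient_id: str
    dob: datetime.date
    sex: str
    has_true_stone: bool = False
    stone_dx_date: datetime.date | None = None
    has_true_gtube: bool = False
    gtube_placement_date: datetime.date | None = None
    feed_months: frozenset[YearMonth] = frozenset()
    nutrition_data_adequate: bool = True

    def validate(self) -> None:
        if self.sex not in ("M", "F"):
            raise ValueError(f"{self.patient_id}: sex must be M or F")
        if self.has_true_stone != (self.stone_dx_date is not None):
            raise ValueError(
                f"{self.patient_id}: stone_dx_date must be present iff has_true_stone"
            )
        if self.has_true_gtube != (self.gtube_placement_date is not None):
            raise ValueError(
                f"{self.patient_id}: gtube_placement_date must be present iff has_true_gtube"
            )
        if self.feed_months and self.gtube_placement_date is None:
            raise ValueError(f"{self.patient_id}: feed months require a G-tube")
        if self.gtube_placement_date is not None:
            pm = ym_index(ym_of(self.gtube_placement_date))
            for m in self.feed_months:
                if ym_index(m) < pm:
                    raise ValueError(
                        f"{self.patient_id}: feed month {format_ym(m)} precedes G-tube placement"
                    )


@dataclass
class MatchResult:
    """Per-case outcome of sequential control review."""

    case_id: str
    control_ids: list[str] = field(default_factory=list)
    n_reviewed_ineligible: int = 0
    exhausted: bool = False

    @property
    def n_matched(self) -> int:
        return len(self.control_ids)
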