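"""Run configuration: generator calibration, eligibility criteria, matching spec.

Defaults reproduce the published study conditions: 177 code-identified
potential cases whose screening dispositions follow the observed attrition
proportions, a 2:1 matched design with date-of-birth (+/-1 year) and sex
matching, and a per-reviewed-candidate control eligibility of 16.5%.
"""
from __future__ import annotations

import dataclasses
import datetime
from dataclasses import dataclass, field
from typing import Any, Mapping

import yaml

from .types import (
    CASE_LABELS,
    CONTROL_EXCLUSION_ORDER,
)


class ConfigurationError(ValueError):
    """Invalid configuration; the message names the offending field."""


#: Observed case screening dispositions (counts over 177 code-identified
#: potential cases) used as the default calibration.
DEFAULT_CASE_COUNTS: dict[str, int] = {
    "INCLUDED": 41,
    "NO_STONE": 28,
    "NO_GTUBE": 3,
    "AGE_RANGE": 42,
    "STUDY_PERIOD": 35,
    "ASYNCHRONOUS": 14,
    "INADEQUATE_DATA": 13,
    "NO_CONTROL": 1,
}

#: Observed exclusion reasons among 406 reviewed-but-ineligible control charts.
DEFAULT_CONTROL_INELIGIBLE_COUNTS: dict[str, int] = {
    "NO_GTUBE": 31,
    "ASYNCHRONOUS": 82,
    "INADEQUATE_DATA": 293,
}


def _normalized(counts: Mapping[str, int]) -> dict[str, float]:
    total = sum(counts.values())
    return {k: v / total for k, v in counts.items()}


@dataclass(frozen=True)
class DateInterval:
    start: datetime.date
    end: datetime.date

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ConfigurationError("date interval: end precedes start")

    def contains(self, d: datetime.date) -> bool:
        return self.start <= d <= self.end


@dataclass(frozen=True)
class FeedRule:
    """Tube-feed exposure rule: >= min_months distinct feed months within the
    window_months calendar months ending at (and including) the index month."""

    min_months: int = 3
    window_months: int = 12

    def __post_init__(self) -> None:
        if self.min_months < 0 or self.window_months < 1:
            raise ConfigurationError("feed_rule: months must be positive")
        if self.min_months > self.window_months:
            raise ConfigurationError("feed_rule: min_months exceeds window_months")


@dataclass(frozen=True)
class EligibilityCriteria:
    """Clinical criteria applied at (simulated) chart review."""

    study_period: DateInterval = DateInterval(
        datetime.date(2005, 1, 1), datetime.date(2011, 12, 31)
    )
    age_range_years: tuple[int, int] = (1, 21)
    feed_rule: FeedRule = FeedRule()

    def __post_init__(self) -> None:
        lo, hi = self.age_range_years
        if lo < 0 or hi < lo:
            raise ConfigurationError("age_range_years: invalid interval")


@dataclass(frozen=True)
class MatchSpec:
    match_ratio: int = 2
    dob_tolerance_days: int = 366
    sex_exact: bool = True
    replacement: bool = False

    def __post_init__(self) -> None:
        if self.match_ratio < 1:
            raise ConfigurationError("match_ratio: must be >= 1")
        if self.dob_tolerance_days < 0:
            raise ConfigurationError("dob_tolerance_days: must be >= 0")


@dataclass(frozen=True)
class FixedControlMargins:
    """Exact control-side margins used under fixed-margins (deterministic)
    allocation: how many included cases fall short of the full match ratio,
    by how many controls each, and the exact ineligible-review counts per
    exclusion reason. Defaults are the observed study margins."""

    n_short_cases: int = 2
    short_by: int = 1
    ineligible_counts: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_CONTROL_INELIGIBLE_COUNTS)
    )

    def __post_init__(self) -> None:
        if self.n_short_cases < 0 or self.short_by < 0:
            raise ConfigurationError("fixed_control_margins: negative count")
        for k in self.ineligible_counts:
            if k not in CONTROL_EXCLUSION_ORDER:
                raise ConfigurationError(
                    f"fixed_control_margins.ineligible_counts: unknown label {k!r}"
                )


@dataclass
class GeneratorConfig:
    """Synthetic-population generator settings.

    ``case_disposition_probs`` is the probability vector over the eight case
    disposition labels; ``control_stream_eligibility`` is the probability that
    a reviewed matched candidate screens eligible, with the complementary mass
    split over the three control exclusion reasons by
    ``control_ineligibility_split``.
    """

    n_potential_cases: int = 177
    case_disposition_probs: dict[str, float] = field(
        default_factory=lambda: _normalized(DEFAULT_CASE_COUNTS)
    )
    control_stream_eligibility: float = 0.165
    control_ineligibility_split: dict[str, float] = field(
        default_factory=lambda: _normalized(DEFAULT_CONTROL_INELIGIBLE_COUNTS)
    )
    study_period: DateInterval = DateInterval(
        datetime.date(2005, 1, 1), datetime.date(2011, 12, 31)
    )
    age_range_years: tuple[int, int] = (1, 21)
    feed_rule: FeedRule = FeedRule()
    match_ratio: int = 2
    dob_tolerance_days: int = 366
    control_pool_cap: int = 100
    horizon_padding_years: tuple[int, int] = (5, 2)
    fixed_control_margins: FixedControlMargins = field(
        default_factory=FixedControlMargins
    )
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        if self.n_potential_cases < 0:
            raise ConfigurationError("n_potential_cases: must be >= 0")
        self._check_probs("case_disposition_probs", self.case_disposition_probs, CASE_LABELS)
        self._check_probs(
            "control_ineligibility_split",
            self.control_ineligibility_split,
            CONTROL_EXCLUSION_ORDER,
        )
        if not 0.0 < self.control_stream_eligibility <= 1.0:
            raise ConfigurationError("control_stream_eligibility: must be in (0, 1]")
        if self.match_ratio < 1:
            raise ConfigurationError("match_ratio: must be >= 1")
        if self.dob_tolerance_days < 0:
            raise ConfigurationError("dob_tolerance_days: must be >= 0")
        if self.control_pool_cap < 0:
            raise ConfigurationError("control_pool_cap: must be >= 0")
        # delegates interval/rule validation to the frozen dataclasses
        EligibilityCriteria(self.study_period, tuple(self.age_range_years), self.feed_rule)

    @staticmethod
    def _check_probs(
        name: str, probs: Mapping[str, float], valid_labels: tuple[str, ...]
    ) -> None:
        for k, v in probs.items():
            if k not in valid_labels:
                raise ConfigurationError(f"{name}: unknown label {k!r}")
            if v < 0:
                raise ConfigurationError(f"{name}: negative probability for {k!r}")
        total = sum(probs.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(f"{name}: probabilities sum to {total!r}, not 1")

    # -- derived views ------------------------------------------------------

    @property
    def criteria(self) -> EligibilityCriteria:
        return EligibilityCriteria(
            self.study_period, tuple(self.age_range_years), self.feed_rule
        )

    @property
    def match_spec(self) -> MatchSpec:
        return MatchSpec(
            match_ratio=self.match_ratio, dob_tolerance_days=self.dob_tolerance_days
        )

    @property
    def horizon(self) -> DateInterval:
        """Simulation horizon: all generated event dates fall inside it."""
        pre, post = self.horizon_padding_years
        start = self.study_period.start.replace(year=self.study_period.start.year - pre)
        end = self.study_period.end.replace(year=self.study_period.end.year + post)
        return DateInterval(start, end)

    # -- (de)serialization --------------------------------------------------

    def to_mapping(self) -> dict[str, Any]:
        def conv(v: Any) -> Any:
            if isinstance(v, datetime.date):
                return v.isoformat()
            if isinstance(v, DateInterval):
                return {"start": v.start.isoformat(), "end": v.end.isoformat()}
            if dataclasses.is_dataclass(v) and not isinstance(v, type):
                return {f.name: conv(getattr(v, f.name)) for f in dataclasses.fields(v)}
            if isinstance(v, Mapping):
                return {k: conv(x) for k, x in v.items()}
            if isinstance(v, tuple):
                return list(v)
            return v

        return {f.name: conv(getattr(self, f.name)) for f in dataclasses.fields(self)}

    @classmethod
    def from_mapping(cls, data: Mapping[str, Any]) -> "GeneratorConfig":
        kwargs: dict[str, Any] = {}
        known = {f.name for f in dataclasses.fields(cls)}
        for key, value in data.items():
            if key not in known:
                raise ConfigurationError(f"unknown configuration key {key!r}")
            kwargs[key] = value
        if "study_period" in kwargs and isinstance(kwargs["study_period"], Mapping):
            sp = kwargs["study_period"]
            kwargs["study_period"] = DateInterval(
                _as_date(sp["start"]), _as_date(sp["end"])
            )
        if "feed_rule" in kwargs and isinstance(kwargs["feed_rule"], Mapping):
            kwargs["feed_rule"] = FeedRule(**kwargs["feed_rule"])
        if "fixed_control_margins" in kwargs and isinstance(
            kwargs["fixed_control_margins"], Mapping
        ):
            kwargs["fixed_control_margins"] = FixedControlMargins(
                **kwargs["fixed_control_margins"]
            )
        for tup_key in ("age_range_years", "horizon_padding_years"):
            if tup_key in kwargs and isinstance(kwargs[tup_key], (list, tuple)):
                kwargs[tup_key] = tuple(kwargs[tup_key])
        return cls(**kwargs)

    @classmethod
    def from_file(cls, path: str) -> "GeneratorConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, Mapping):
            raise ConfigurationError(f"config file {path}: expected a mapping")
        return cls.from_mapping(data)


def _as_date(v: Any) -> datetime.date:
    if isinstance(v, datetime.date):
        return v
    return datetime.date.fromisoformat(str(v))
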