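"""Two-stage matched control selection.

Stage one is automated: filter the candidate pool to same-sex candidates born
within the date-of-birth tolerance of the case. Stage two is sequential
review: screen randomly ordered candidates one at a time until the match
ratio is reached or the pool is exhausted, counting the ineligible charts
reviewed along the way. By default controls are allocated without
replacement (a selected control serves exactly one case).
"""
from __future__ import annotations

import random
from collections import Counter
from typing import Callable, Iterable, Mapping, Sequence

from ._rand import derive_seed
from .config import EligibilityCriteria, MatchSpec
from .review import assess_control
from .types import CodedEvent, Disposition, MatchResult, PatientRecord

#: One reviewed chart: (record, its coded events, its screening disposition).
ReviewedChart = tuple[PatientRecord, list[CodedEvent], Disposition]

#: Candidate stream factory: (case, per-case rng) -> iterable of candidates,
#: each a PatientRecord or a (PatientRecord, events, ...) tuple.
CandidateSource = Callable[[PatientRecord, random.Random], Iterable]


def automated_match_pool(
    case: PatientRecord,
    candidates: Sequence[PatientRecord],
    spec: MatchSpec = MatchSpec(),
) -> list[str]:
    """Candidate ids matching the case on sex and DOB tolerance, input order
    preserved."""
    out = []
    for c in candidates:
        if spec.sex_exact and c.sex != case.sex:
            continue
        if abs((c.dob - case.dob).days) > spec.dob_tolerance_days:
            continue
        out.append(c.patient_id)
    return out


def _unpack(item) -> tuple[PatientRecord, list[CodedEvent]]:
    if isinstance(item, PatientRecord):
        return item, []
    return item[0], list(item[1])


def sequential_review(
    case: PatientRecord,
    candidates: Iterable,
    criteria: EligibilityCriteria,
    spec: MatchSpec = MatchSpec(),
    rng: random.Random | None = None,
    consumed: set[str] | None = None,
    reviewed: list[ReviewedChart] | None = None,
) -> MatchResult:
    """Screen candidates in sequence until the match ratio is met.

    If ``candidates`` is a concrete sequence and ``rng`` is given, it is
    shuffled first (randomized review order); lazy streams are consumed as
    generated. Candidates already present in ``consumed`` are skipped without
    review; accepted controls are added to it when replacement is off.
    ``reviewed`` collects every screened chart with its disposition.
    """
    if isinstance(candidates, (list, tuple)):
        pool = list(candidates)
        if rng is not None:
            rng.shuffle(pool)
        stream: Iterable = pool
    else:
        stream = candidates

    control_ids: list[str] = []
    n_ineligible = 0
    for item in stream:
        record, events = _unpack(item)
        if consumed is not None and record.patient_id in consumed:
            continue
        disp = assess_control(record, criteria, case.stone_dx_date)
        if reviewed is not None:
            reviewed.append((record, events, disp))
        if disp.label == "ELIGIBLE":
            control_ids.append(record.patient_id)
            if consumed is not None and not spec.replacement:
                consumed.add(record.patient_id)
            if len(control_ids) >= spec.match_ratio:
                break
        else:
            n_ineligible += 1
    return MatchResult(
        case_id=case.patient_id,
        control_ids=control_ids,
        n_reviewed_ineligible=n_ineligible,
        exhausted=len(control_ids) < spec.match_ratio,
    )


def run_matching(
    cases: Sequence[PatientRecord],
    candidate_source: CandidateSource,
    criteria: EligibilityCriteria,
    spec: MatchSpec = MatchSpec(),
    rng: random.Random | None = None,
) -> tuple[list[MatchResult], dict[str, int], dict[str, list[ReviewedChart]]]:
    """Match every case, in sorted-id order, against its candidate stream.

    Returns per-case match results, the tally of control exclusion reasons
    over all reviewed charts, and the reviewed charts per case. Each case's
    stream gets its own RNG derived from a base draw, so results do not
    depend on how many random numbers earlier cases consumed.
    """
    ids = [c.patient_id for c in cases]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate case ids in matching input")
    ordered = sorted(cases, key=lambda c: c.patient_id)
    if rng is None:
        rng = random.Random(0)
    base = rng.randrange(2**31)
    consumed: set[str] = set()

    results: list[MatchResult] = []
    tallies: Counter[str] = Counter()
    reviewed_by_case: dict[str, list[ReviewedChart]] = {}
    for case in ordered:
        case_rng = random.Random(derive_seed(base, case.patient_id))
        candidates = candidate_source(case, case_rng)
        reviewed: list[ReviewedChart] = []
        shuffle_rng = case_rng if isinstance(candidates, (list, tuple)) else None
        res = sequential_review(
            case,
            candidates,
            criteria,
            spec,
            rng=shuffle_rng,
            consumed=consumed,
            reviewed=reviewed,
        )
        for _, _, disp in reviewed:
            if disp.label != "ELIGIBLE":
                tallies[disp.label] += 1
        results.append(res)
        reviewed_by_case[case.patient_id] = reviewed
    return results, dict(tallies), reviewed_by_case


def relabel_unmatched_cases(
    screen_labels: Mapping[str, str], results: Sequence[MatchResult]
) -> dict[str, str]:
    """Final case labels after matching: included cases that ended with zero
    controls become NO_CONTROL."""
    by_case = {r.case_id: r for r in results}
    out = dict(screen_labels)
    for cid, label in screen_labels.items():
        if label == "INCLUDED":
            res = by_case.get(cid)
            if res is None or res.n_matched == 0:
                out[cid] = "NO_CONTROL"
    return out


def mean_ineligible_reviews(
    results: Sequence[MatchResult], include_accepted: bool = False
) -> float:
    """Mean charts reviewed per matched case (cases that retained at least one
    control). By default counts ineligible reviews only; with
    ``include_accepted`` the accepted controls are counted as reviews too."""
    matched = [r for r in results if r.n_matched > 0]
    if not matched:
        raise ValueError("no matched cases")
    total = sum(
        r.n_reviewed_ineligible + (r.n_matched if include_accepted else 0)
        for r in matched
    )
    return total / len(matched)
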