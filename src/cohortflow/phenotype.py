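"""Boolean code-set queries over the coded-event layer.

Emulates a clinical-research query tool at the level that matters for cohort
assembly: named sets of (code system, code) pairs combined into
require/forbid queries, evaluated either as a de-identified count or as an
identified patient list. Codes are matched as exact normalized strings
(trimmed, case-folded); no hierarchy or prefix expansion is performed because
the study's code lists are fully enumerated.
"""
from __future__ import annotations

import csv
from dataclasses import dataclass
from typing import Iterable, Mapping

from .config import DateInterval
from .types import CodedEvent, VALID_CODE_SYSTEMS

CodePair = tuple[str, str]


def normalize_code(code_system: str, code: str) -> CodePair:
    return (code_system.strip().upper(), code.strip().upper())


@dataclass(frozen=True)
class CodeSet:
    """A named set of (code_system, code) pairs; membership is case-insensitive."""

    name: str
    members: frozenset[CodePair]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"code set {self.name!r} is empty")
        object.__setattr__(
            self, "members", frozenset(normalize_code(s, c) for s, c in self.members)
        )

    def matches(self, event: CodedEvent) -> bool:
        return normalize_code(event.code_system, event.code) in self.members


@dataclass(frozen=True)
class PhenotypeQuery:
    """Require/forbid query: every require set must hit >= 1 event; no event
    may hit any forbid set."""

    require: tuple[CodeSet, ...]
    forbid: tuple[CodeSet, ...] = ()

    def __post_init__(self) -> None:
        if not self.require:
            raise ValueError("query must have at least one require set")


# G-tube diagnosis/procedure codes as enumerated for the study. The printed
# ICD-9 list mixes diagnosis (V44.1, V55.1, 536.4x) and procedure (43.x, 96.36,
# 97.02) codes and repeats 43.19 once; the duplicate collapses on storage.
_GTUBE_ICD9: tuple[CodePair, ...] = (
    ("ICD9-DX", "V44.1"),
    ("ICD9-PX", "43.19"),
    ("ICD9-PX", "43.11"),
    ("ICD9-PX", "43.19"),  # printed twice in the source list
    ("ICD9-DX", "V55.1"),
    ("ICD9-PX", "96.36"),
    ("ICD9-PX", "97.02"),
    ("ICD9-DX", "536.40"),
    ("ICD9-DX", "536.41"),
    ("ICD9-DX", "536.42"),
    ("ICD9-DX", "536.49"),
)

_GTUBE_CPT: tuple[CodePair, ...] = (
    ("CPT", "43246"),
    ("CPT", "43653"),
    ("CPT", "43750"),
    ("CPT", "43760"),
    ("CPT", "43830"),
    ("CPT", "43831"),
    ("CPT", "43832"),
    ("CPT", "49440"),
    ("CPT", "49450"),
    ("CPT", "49465"),
    ("CPT", "74350"),
)

_STONE_ICD9: tuple[CodePair, ...] = (
    ("ICD9-DX", "592.1"),
    ("ICD9-DX", "592.2"),
    ("ICD9-DX", "592.9"),
)


def default_code_sets() -> dict[str, CodeSet]:
    """The study's code sets: G-tube ICD-9 (10 unique codes), G-tube CPT (11)
    and kidney-stone ICD-9 diagnoses (3)."""
    return {
        "GTUBE_ICD9": CodeSet("GTUBE_ICD9", frozenset(_GTUBE_ICD9)),
        "GTUBE_CPT": CodeSet("GTUBE_CPT", frozenset(_GTUBE_CPT)),
        "STONE_ICD9": CodeSet("STONE_ICD9", frozenset(_STONE_ICD9)),
    }


def gtube_code_set() -> CodeSet:
    """Union G-tube set (>= 1 ICD-9 *or* CPT code qualifies)."""
    sets = default_code_sets()
    return CodeSet(
        "GTUBE_ANY", sets["GTUBE_ICD9"].members | sets["GTUBE_CPT"].members
    )


def case_query() -> PhenotypeQuery:
    """Potential cases: >= 1 G-tube code and >= 1 kidney-stone diagnosis code."""
    return PhenotypeQuery(require=(gtube_code_set(), default_code_sets()["STONE_ICD9"]))


def control_query() -> PhenotypeQuery:
    """Potential controls: >= 1 G-tube code in the absence of any stone code."""
    return PhenotypeQuery(
        require=(gtube_code_set(),), forbid=(default_code_sets()["STONE_ICD9"],)
    )


def evaluate_query(
    events: Iterable[CodedEvent],
    query: PhenotypeQuery,
    date_window: DateInterval | None = None,
) -> set[str]:
    """Identified mode: the set of patient ids satisfying the query.

    ``date_window`` optionally restricts which events are visible to the query
    (off by default: the study applied date criteria only at chart review).
    """
    per_patient: dict[str, set[CodePair]] = {}
    for i, ev in enumerate(events):
        system = ev.code_system.strip().upper()
        if system not in VALID_CODE_SYSTEMS:
            raise ValueError(
                f"event row {i} (patient {ev.patient_id}): unknown code system "
                f"{ev.code_system!r}"
            )
        if date_window is not None and not date_window.contains(ev.date):
            continue
        per_patient.setdefault(ev.patient_id, set()).add(
            normalize_code(ev.code_system, ev.code)
        )
    result: set[str] = set()
    for pid, codes in per_patient.items():
        if all(codes & cs.members for cs in query.require) and not any(
            codes & cs.members for cs in query.forbid
        ):
            result.add(pid)
    return result


def count_query(
    events: Iterable[CodedEvent],
    query: PhenotypeQuery,
    date_window: DateInterval | None = None,
) -> int:
    """De-identified mode: number of patients satisfying the query."""
    return len(evaluate_query(events, query, date_window))


def load_code_set(path: str, name: str | None = None) -> CodeSet:
    """Load a code set from a two-column (code_system, code) delimited file.

    A header row reading ``code_system<TAB>code`` is skipped if present.
    """
    members: set[CodePair] = set()
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        for row in reader:
            if not row or row[0].startswith("#"):
                continue
            if row[0].strip().lower() == "code_system":
                continue
            if len(row) < 2:
                raise ValueError(f"{path}: expected two columns, got {row!r}")
            members.add((row[0], row[1]))
    if name is None:
        name = path.rsplit("/", 1)[-1].rsplit(".", 1)[0]
    return CodeSet(name, frozenset(members))
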