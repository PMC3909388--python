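"""Delimited-text readers and writers for every pipeline artifact.

All files are TSV with a header row; dates are ISO-8601; feed months are
serialized as comma-separated YYYY-MM tokens; booleans as true/false.
"""
from __future__ import annotations

import csv
import datetime
from typing import Iterable, Mapping, Sequence

from .types import (
    CodedEvent,
    Disposition,
    MatchResult,
    PatientRecord,
    format_ym,
    parse_ym,
)


def _opt_date(s: str) -> datetime.date | None:
    return datetime.date.fromisoformat(s) if s else None


def _fmt_opt(d: datetime.date | None) -> str:
    return d.isoformat() if d is not None else ""


def _bool(s: str) -> bool:
    if s in ("true", "false"):
        return s == "true"
    raise ValueError(f"expected true/false, got {s!r}")


def _writer(fh):
    return csv.writer(fh, delimiter="\t", lineterminator="\n")


def _rows(path: str) -> Iterable[dict[str, str]]:
    with open(path, "r", encoding="utf-8", newline="") as fh:
        yield from csv.DictReader(fh, delimiter="\t")


# -- demographics / truth ----------------------------------------------------


def write_demographics(path: str, records: Sequence[PatientRecord]) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = _writer(fh)
        w.writerow(["patient_id", "dob", "sex"])
        for r in records:
            w.writerow([r.patient_id, r.dob.isoformat(), r.sex])


def write_truth(path: str, records: Sequence[PatientRecord]) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = _writer(fh)
        w.writerow(
            [
                "patient_id",
                "has_true_stone",
                "stone_dx_date",
                "has_true_gtube",
                "gtube_placement_date",
                "feed_months",
                "nutrition_data_adequate",
            ]
        )
        for r in records:
            w.writerow(
                [
                    r.patient_id,
                    str(r.has_true_stone).lower(),
                    _fmt_opt(r.stone_dx_date),
                    str(r.has_true_gtube).lower(),
                    _fmt_opt(r.gtube_placement_date),
                    ",".join(format_ym(m) for m in sorted(r.feed_months)),
                    str(r.nutrition_data_adequate).lower(),
                ]
            )


def read_patients(demographics_path: str, truth_path: str) -> dict[str, PatientRecord]:
    """Join demographics and truth into full records, keyed by patient id."""
    demo: dict[str, tuple[datetime.date, str]] = {}
    for row in _rows(demographics_path):
        demo[row["patient_id"]] = (datetime.date.fromisoformat(row["dob"]), row["sex"])
    out: dict[str, PatientRecord] = {}
    for row in _rows(truth_path):
        pid = row["patient_id"]
        if pid not in demo:
            raise ValueError(f"truth row for {pid} has no demographics row")
        dob, sex = demo[pid]
        months = frozenset(
            parse_ym(tok) for tok in row["feed_months"].split(",") if tok
        )
        rec = PatientRecord(
            patient_id=pid,
            dob=dob,
            sex=sex,
            has_true_stone=_bool(row["has_true_stone"]),
            stone_dx_date=_opt_date(row["stone_dx_date"]),
            has_true_gtube=_bool(row["has_true_gtube"]),
            gtube_placement_date=_opt_date(row["gtube_placement_date"]),
            feed_months=months,
            nutrition_data_adequate=_bool(row["nutrition_data_adequate"]),
        )
        rec.validate()
        out[pid] = rec
    return out


# -- coded events ------------------------------------------------------------


def write_events(path: str, events: Sequence[CodedEvent]) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = _writer(fh)
        w.writerow(["patient_id", "code_system", "code", "date"])
        for e in events:
            w.writerow([e.patient_id, e.code_system, e.code, e.date.isoformat()])


def read_events(path: str) -> list[CodedEvent]:
    return [
        CodedEvent(
            row["patient_id"],
            row["code_system"],
            row["code"],
            datetime.date.fromisoformat(row["date"]),
        )
        for row in _rows(path)
    ]


# -- dispositions / labels ---------------------------------------------------


def write_dispositions(
    path: str, rows: Sequence[tuple[str, Disposition, str]]
) -> None:
    """Rows are (patient_id, disposition, matched_case_id-or-empty)."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = _writer(fh)
        w.writerow(["patient_id", "role", "label", "matched_case_id"])
        for pid, disp, case_id in rows:
            w.writerow([pid, disp.role, disp.label, case_id])


def read_dispositions(path: str) -> list[tuple[str, Disposition, str]]:
    return [
        (row["patient_id"], Disposition(row["label"], row["role"]), row["matched_case_id"])
        for row in _rows(path)
    ]


def write_intended_labels(path: str, intended: Mapping[str, str]) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = _writer(fh)
        w.writerow(["patient_id", "intended_label"])
        for pid in sorted(intended):
            w.writerow([pid, intended[pid]])


def read_intended_labels(path: str) -> dict[str, str]:
    return {row["patient_id"]: row["intended_label"] for row in _rows(path)}


# -- matching ----------------------------------------------------------------


def write_matches(path: str, results: Sequence[MatchResult]) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = _writer(fh)
        w.writerow(["case_id", "control_id", "match_order"])
        for res in results:
            for order, cid in enumerate(res.control_ids, start=1):
                w.writerow([res.case_id, cid, order])


def write_review_stats(path: str, results: Sequence[MatchResult]) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = _writer(fh)
        w.writerow(["case_id", "n_reviewed_ineligible", "n_matched", "exhausted"])
        for res in results:
            w.writerow(
                [
                    res.case_id,
                    res.n_reviewed_ineligible,
                    res.n_matched,
                    str(res.exhausted).lower(),
                ]
            )


def read_review_stats(path: str) -> list[MatchResult]:
    out = []
    for row in _rows(path):
        out.append(
            MatchResult(
                case_id=row["case_id"],
                control_ids=[""] * int(row["n_matched"]),
                n_reviewed_ineligible=int(row["n_reviewed_ineligible"]),
                exhausted=_bool(row["exhausted"]),
            )
        )
    return out


def read_matches(path: str) -> dict[str, list[str]]:
    out: dict[str, list[str]] = {}
    for row in _rows(path):
        out.setdefault(row["case_id"], []).append(row["control_id"])
    return out
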