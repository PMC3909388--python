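"""Attrition accounting: counts and rounded percentages per disposition.

Produces the study's two attrition views: a per-reason exclusion table
(cases and controls side by side, percentages of the exclusion total) and a
linear flow summary (identified -> excluded -> included, with the headline
inclusion fraction). Percentages are always recomputed from counts with
half-up rounding, never stored and re-used.
"""
from __future__ import annotations

import csv
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

from .types import (
    CASE_EXCLUSION_ORDER,
    CONTROL_EXCLUSION_ORDER,
    INACCURATE_QUERY_LABELS,
    LABEL_TITLES,
    Disposition,
)


def percent(numerator: int, denominator: int, decimals: int = 1) -> float:
    """100 * numerator / denominator, rounded half-up to ``decimals``."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    q = Decimal(1).scaleb(-decimals)
    value = (Decimal(numerator) * 100 / Decimal(denominator)).quantize(
        q, rounding=ROUND_HALF_UP
    )
    return float(value)


@dataclass(frozen=True)
class FlowRow:
    label: str
    count: int
    percent_of_excluded: float | None  # None when nothing was excluded


@dataclass
class FlowTable:
    """Attrition table for one role: counts per exclusion reason plus the
    identified/excluded/included margins."""

    role: str
    n_identified: int
    n_excluded: int
    n_included: int
    rows: list[FlowRow] = field(default_factory=list)
    decimals: int = 1

    @property
    def headline_percent(self) -> float | None:
        """Included as a percentage of all identified (None if none identified)."""
        if self.n_identified <= 0:
            return None
        return percent(self.n_included, self.n_identified, self.decimals)

    @property
    def inaccurate_query_count(self) -> int:
        return sum(r.count for r in self.rows if r.label in INACCURATE_QUERY_LABELS)

    @property
    def inaccurate_query_percent(self) -> float | None:
        if self.n_excluded <= 0:
            return None
        return percent(self.inaccurate_query_count, self.n_excluded, self.decimals)

    def check(self) -> None:
        if self.n_identified != self.n_excluded + self.n_included:
            raise ValueError("flow table: identified != excluded + included")
        if sum(r.count for r in self.rows) != self.n_excluded:
            raise ValueError("flow table: row counts do not sum to excluded")


def tabulate_flow(
    dispositions: Iterable[Disposition], role: str, decimals: int = 1
) -> FlowTable:
    """Build the attrition table for one role from per-candidate dispositions."""
    order = CASE_EXCLUSION_ORDER if role == "case" else CONTROL_EXCLUSION_ORDER
    included_label = "INCLUDED" if role == "case" else "ELIGIBLE"
    counts = {lab: 0 for lab in order}
    n_included = 0
    n_total = 0
    for disp in dispositions:
        if disp.role != role:
            raise ValueError(f"disposition role {disp.role!r} mixed into {role!r} table")
        n_total += 1
        if disp.label == included_label:
            n_included += 1
        else:
            counts[disp.label] += 1
    n_excluded = n_total - n_included
    rows = [
        FlowRow(
            lab,
            counts[lab],
            percent(counts[lab], n_excluded, decimals) if n_excluded > 0 else None,
        )
        for lab in order
    ]
    table = FlowTable(role, n_total, n_excluded, n_included, rows, decimals)
    table.check()
    return table


# ---------------------------------------------------------------------------
# rendering and serialization


# (section title, row labels, merge-row-into-section-line)
_SECTIONS: tuple[tuple[str, tuple[str, ...], bool], ...] = (
    ("Inaccurate query", ("NO_STONE", "NO_GTUBE"), False),
    ("Did not meet inclusion criteria", ("AGE_RANGE", "STUDY_PERIOD", "ASYNCHRONOUS"), False),
    ("Inadequate clinical data", ("INADEQUATE_DATA",), True),
    ("Other", ("NO_CONTROL",), False),
)


def _cell(table: FlowTable | None, label: str) -> str:
    if table is None:
        return "NA"
    row = next((r for r in table.rows if r.label == label), None)
    if row is None:
        return "NA"
    pct = "-" if row.percent_of_excluded is None else f"{row.percent_of_excluded:.{table.decimals}f}"
    return f"{row.count} ({pct})"


def _summary_line(table: FlowTable) -> str:
    verb = "identified" if table.role == "case" else "reviewed"
    head = (
        f"{table.headline_percent:.{table.decimals}f}% of {verb}"
        if table.headline_percent is not None
        else "NA"
    )
    return (
        f"{table.role.capitalize()}s: {table.n_identified} {verb} -> "
        f"{table.n_excluded} excluded -> {table.n_included} included ({head})"
    )


def render_flow(tables: Sequence[FlowTable]) -> str:
    """Aligned-text report: side-by-side exclusion-reason table plus the
    linear flow summary."""
    cases = next((t for t in tables if t.role == "case"), None)
    controls = next((t for t in tables if t.role == "control"), None)
    col0, col1, col2 = 36, 38, 38

    lines = ["Reasons for exclusion of potential study participants"]
    header = (
        f"{'Reason for exclusion':<{col0}}"
        f"{('Excluded potential cases' + (f' (N = {cases.n_excluded})' if cases else '')):<{col1}}"
        f"{('Excluded potential controls' + (f' (N = {controls.n_excluded})' if controls else '')):<{col2}}"
    )
    lines.append(header)
    lines.append("-" * len(header.rstrip()))
    for section, labels, merge in _SECTIONS:
        if not merge:
            lines.append(section)
        for lab in labels:
            title = section if merge else "  " + LABEL_TITLES[lab]
            lines.append(
                f"{title:<{col0}}{_cell(cases, lab):<{col1}}{_cell(controls, lab):<{col2}}"
            )
    lines.append("")
    for t in (cases, controls):
        if t is not None:
            lines.append(_summary_line(t))
    for t in (cases, controls):
        if t is not None and t.inaccurate_query_percent is not None:
            lines.append(
                f"{t.role.capitalize()} exclusions from inaccurate coding: "
                f"{t.inaccurate_query_count} ({t.inaccurate_query_percent:.{t.decimals}f}%)"
            )
    return "\n".join(lines) + "\n"


def write_flow_tsv(table: FlowTable, path: str) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["role", "kind", "label", "count", "percent"])
        hp = table.headline_percent
        w.writerow([table.role, "summary", "identified", table.n_identified, ""])
        w.writerow([table.role, "summary", "excluded", table.n_excluded, ""])
        w.writerow(
            [table.role, "summary", "included", table.n_included, "" if hp is None else hp]
        )
        for r in table.rows:
            w.writerow(
                [
                    table.role,
                    "row",
                    r.label,
                    r.count,
                    "" if r.percent_of_excluded is None else r.percent_of_excluded,
                ]
            )


def read_flow_tsv(path: str) -> FlowTable:
    summary: dict[str, int] = {}
    rows: list[FlowRow] = []
    role = ""
    with open(path, "r", encoding="utf-8", newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            role = row["role"]
            if row["kind"] == "summary":
                summary[row["label"]] = int(row["count"])
            else:
                pct = float(row["percent"]) if row["percent"] else None
                rows.append(FlowRow(row["label"], int(row["count"]), pct))
    table = FlowTable(
        role, summary["identified"], summary["excluded"], summary["included"], rows
    )
    table.check()
    return table
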