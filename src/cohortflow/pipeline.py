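"""Pipeline orchestration: generate -> query -> screen -> match -> report.

Each stage reads only the delimited files of earlier stages, so any stage can
be re-run from intermediate outputs and reproduce the full pipeline's files.
A machine-readable manifest records the configuration snapshot, seed, file
paths and record counts for every stage.
"""
from __future__ import annotations

import dataclasses
import datetime
import json
import logging
import os
import random
import statistics
from dataclasses import dataclass, field
from typing import Iterable

from . import io as cfio
from ._rand import derive_seed
from .config import GeneratorConfig
from .flow import FlowTable, render_flow, tabulate_flow, write_flow_tsv
from .generate import (
    allocate_fixed_control_streams,
    fixed_control_stream,
    generate_control_stream,
    generate_population,
)
from .matching import (
    mean_ineligible_reviews,
    relabel_unmatched_cases,
    run_matching,
)
from .phenotype import case_query, count_query, evaluate_query
from .types import Disposition, PatientRecord
from .review import assess_case

logger = logging.getLogger("cohortflow")

STAGES = ("generate", "query", "screen", "match", "report")


@dataclass
class StageInfo:
    outputs: dict[str, str] = field(default_factory=dict)
    counts: dict[str, int] = field(default_factory=dict)


@dataclass
class RunManifest:
    seed: int
    config: dict
    fixed_margins: bool
    started_utc: str = ""
    finished_utc: str = ""
    stages: dict[str, StageInfo] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True) + "\n"

    def write(self, path: str) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(self.to_json())


def _path(outdir: str, name: str) -> str:
    return os.path.join(outdir, name)


# ---------------------------------------------------------------------------
# stages


def stage_generate(
    config: GeneratorConfig, outdir: str, fixed_margins: bool = False
) -> StageInfo:
    records, events, intended = generate_population(config, fixed_margins=fixed_margins)
    info = StageInfo()
    for name, writer, data in (
        ("demographics", cfio.write_demographics, records),
        ("truth", cfio.write_truth, records),
        ("events", cfio.write_events, events),
    ):
        p = _path(outdir, f"{name}.tsv")
        writer(p, data)
        info.outputs[name] = p
    p = _path(outdir, "intended_labels.tsv")
    cfio.write_intended_labels(p, intended)
    info.outputs["intended_labels"] = p
    info.counts = {"patients": len(records), "events": len(events)}
    logger.info("generate: %d patients, %d coded events", len(records), len(events))
    return info


def stage_query(outdir: str, identified: bool = True) -> StageInfo:
    events = cfio.read_events(_path(outdir, "events.tsv"))
    query = case_query()
    info = StageInfo()
    if identified:
        ids = sorted(evaluate_query(events, query))
        p = _path(outdir, "case_candidates.txt")
        with open(p, "w", encoding="utf-8") as fh:
            fh.writelines(f"{pid}\n" for pid in ids)
        info.outputs["case_candidates"] = p
        info.counts["case_query"] = len(ids)
    else:
        info.counts["case_query"] = count_query(events, query)
    logger.info("query: %d patients match the case phenotype", info.counts["case_query"])
    return info


def stage_screen(config: GeneratorConfig, outdir: str) -> StageInfo:
    patients = cfio.read_patients(
        _path(outdir, "demographics.tsv"), _path(outdir, "truth.tsv")
    )
    with open(_path(outdir, "case_candidates.txt"), "r", encoding="utf-8") as fh:
        candidate_ids = [line.strip() for line in fh if line.strip()]
    criteria = config.criteria
    rows = []
    for pid in candidate_ids:
        disp = assess_case(patients[pid], criteria)
        rows.append((pid, disp, ""))
    p = _path(outdir, "case_dispositions.tsv")
    cfio.write_dispositions(p, rows)
    info = StageInfo(outputs={"case_dispositions": p}, counts={"screened": len(rows)})
    logger.info("screen: %d potential cases screened", len(rows))
    return info


def stage_match(
    config: GeneratorConfig, outdir: str, fixed_margins: bool = False
) -> StageInfo:
    patients = cfio.read_patients(
        _path(outdir, "demographics.tsv"), _path(outdir, "truth.tsv")
    )
    dispositions = cfio.read_dispositions(_path(outdir, "case_dispositions.tsv"))
    intended = cfio.read_intended_labels(_path(outdir, "intended_labels.tsv"))
    included = [pid for pid, disp, _ in dispositions if disp.label == "INCLUDED"]
    # pools of cases generated as includable-but-unmatchable stay empty
    poolable = [pid for pid in included if intended.get(pid) != "NO_CONTROL"]
    cases = [patients[pid] for pid in included]

    plan = None
    if fixed_margins:
        plan_rng = random.Random(derive_seed(config.seed, "match-plan"))
        plan = allocate_fixed_control_streams(poolable, config, plan_rng)

    def source(case: PatientRecord, case_rng: random.Random) -> Iterable:
        if intended.get(case.patient_id) == "NO_CONTROL":
            return iter(())
        if plan is not None:
            return fixed_control_stream(case, plan[case.patient_id], config, case_rng)
        return generate_control_stream(case, config, case_rng)

    rng = random.Random(derive_seed(config.seed, "match"))
    results, tallies, reviewed = run_matching(
        cases, source, config.criteria, config.match_spec, rng
    )

    control_records, control_events, control_rows = [], [], []
    for case_id in sorted(reviewed):
        for record, events, disp in reviewed[case_id]:
            control_records.append(record)
            control_events.extend(events)
            control_rows.append((record.patient_id, disp, case_id))

    info = StageInfo()
    p = _path(outdir, "matches.tsv")
    cfio.write_matches(p, results)
    info.outputs["matches"] = p
    p = _path(outdir, "review_stats.tsv")
    cfio.write_review_stats(p, results)
    info.outputs["review_stats"] = p
    p = _path(outdir, "control_dispositions.tsv")
    cfio.write_dispositions(p, control_rows)
    info.outputs["control_dispositions"] = p
    for name, writer, data in (
        ("control_demographics", cfio.write_demographics, control_records),
        ("control_truth", cfio.write_truth, control_records),
        ("control_events", cfio.write_events, control_events),
    ):
        p = _path(outdir, f"{name}.tsv")
        writer(p, data)
        info.outputs[name] = p
    n_controls = sum(r.n_matched for r in results)
    info.counts = {
        "cases_entering_matching": len(cases),
        "controls_matched": n_controls,
        "control_charts_reviewed": len(control_rows),
    }
    logger.info(
        "match: %d cases -> %d controls (%d charts reviewed)",
        len(cases),
        n_controls,
        len(control_rows),
    )
    return info


def stage_report(config: GeneratorConfig, outdir: str) -> StageInfo:
    case_disps = cfio.read_dispositions(_path(outdir, "case_dispositions.tsv"))
    results = cfio.read_review_stats(_path(outdir, "review_stats.tsv"))
    screen_labels = {pid: disp.label for pid, disp, _ in case_disps}
    final_labels = relabel_unmatched_cases(screen_labels, results)
    case_table = tabulate_flow(
        (Disposition(lab, "case") for lab in final_labels.values()), "case"
    )
    control_disps = cfio.read_dispositions(_path(outdir, "control_dispositions.tsv"))
    control_table = tabulate_flow((disp for _, disp, _ in control_disps), "control")

    info = StageInfo()
    for table, name in ((case_table, "flow_cases"), (control_table, "flow_controls")):
        p = _path(outdir, f"{name}.tsv")
        write_flow_tsv(table, p)
        info.outputs[name] = p

    text = render_flow([case_table, control_table])
    matched = [r for r in results if r.n_matched > 0]
    if matched:
        mean = mean_ineligible_reviews(results)
        sd = (
            statistics.stdev(r.n_reviewed_ineligible for r in matched)
            if len(matched) > 1
            else 0.0
        )
        text += (
            f"Control charts reviewed per matched case (ineligible only): "
            f"mean {mean:.1f}, sd {sd:.1f} (n = {len(matched)} matched cases)\n"
        )
    p = _path(outdir, "report.txt")
    with open(p, "w", encoding="utf-8") as fh:
        fh.write(text)
    info.outputs["report"] = p
    info.counts = {
        "cases_included": case_table.n_included,
        "controls_included": control_table.n_included,
    }
    logger.info(
        "report: %d cases, %d controls in the final cohort",
        case_table.n_included,
        control_table.n_included,
    )
    return info


# ---------------------------------------------------------------------------


def run_pipeline(
    config: GeneratorConfig,
    outdir: str,
    seed: int | None = None,
    fixed_margins: bool = False,
) -> RunManifest:
    """Execute all five stages in order, writing every artifact to ``outdir``."""
    if seed is not None:
        config = dataclasses.replace(config, seed=seed)
    os.makedirs(outdir, exist_ok=True)
    manifest = RunManifest(
        seed=config.seed,
        config=config.to_mapping(),
        fixed_margins=fixed_margins,
        started_utc=datetime.datetime.now(datetime.timezone.utc).isoformat(),
    )
    stage_fns = {
        "generate": lambda: stage_generate(config, outdir, fixed_margins),
        "query": lambda: stage_query(outdir),
        "screen": lambda: stage_screen(config, outdir),
        "match": lambda: stage_match(config, outdir, fixed_margins),
        "report": lambda: stage_report(config, outdir),
    }
    for name in STAGES:
        try:
            manifest.stages[name] = stage_fns[name]()
        except Exception:
            logger.exception("stage %r failed", name)
            manifest.finished_utc = datetime.datetime.now(datetime.timezone.utc).isoformat()
            manifest.write(_path(outdir, "manifest.json"))
            raise
    manifest.finished_utc = datetime.datetime.now(datetime.timezone.utc).isoformat()
    manifest.write(_path(outdir, "manifest.json"))
    return manifest
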