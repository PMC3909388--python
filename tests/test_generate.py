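"""Synthetic-EHR generator: calibration, round-trip fidelity, determinism."""
import math
import random

import pytest

from cohortflow import (
    CASE_LABELS,
    ConfigurationError,
    GeneratorConfig,
    assess_case,
    assess_control,
    case_query,
    control_query,
    evaluate_query,
    generate_control_stream,
    generate_population,
    realize_case_disposition,
)
from cohortflow.generate import (
    allocate_fixed_control_streams,
    largest_remainder_counts,
)
from cohortflow import io as cfio


def expected_screen_label(intended):
    # control availability is resolved in matching, not at chart review
    return "INCLUDED" if intended == "NO_CONTROL" else intended


class TestGeneratePopulation:
    def test_default_population_size_and_query(self, config):
        records, events, intended = generate_population(config)
        assert len(records) == 177
        assert len(intended) == 177
        # every generated potential case satisfies the case phenotype query
        assert evaluate_query(events, case_query()) == {r.patient_id for r in records}

    def test_degenerate_distribution_all_included(self):
        probs = {lab: 0.0 for lab in CASE_LABELS}
        probs["INCLUDED"] = 1.0
        cfg = GeneratorConfig(n_potential_cases=5, case_disposition_probs=probs, seed=9)
        records, _, intended = generate_population(cfg)
        assert len(records) == 5
        assert all(assess_case(r, cfg.criteria).label == "INCLUDED" for r in records)
        assert set(intended.values()) == {"INCLUDED"}

    def test_round_trip_disposition_equals_intended(self, config):
        records, _, intended = generate_population(config)
        crit = config.criteria
        for r in records:
            assert (
                assess_case(r, crit).label
                == expected_screen_label(intended[r.patient_id])
            )

    def test_multinomial_calibration_within_three_se(self):
        n = 4000
        cfg = GeneratorConfig(n_potential_cases=n, seed=71)
        _, _, intended = generate_population(cfg)
        for lab, p in cfg.case_disposition_probs.items():
            obs = sum(1 for v in intended.values() if v == lab) / n
            se = math.sqrt(p * (1 - p) / n)
            assert abs(obs - p) <= 3 * se, (lab, obs, p)

    def test_invalid_probability_vector_names_field(self):
        probs = {lab: 0.0 for lab in CASE_LABELS}
        probs["INCLUDED"] = 0.7  # sums to 0.7
        with pytest.raises(ConfigurationError, match="case_disposition_probs"):
            GeneratorConfig(case_disposition_probs=probs)
        with pytest.raises(ConfigurationError, match="case_disposition_probs"):
            GeneratorConfig(case_disposition_probs={"BOGUS": 1.0})

    def test_unknown_label_rejected(self, config):
        with pytest.raises(ValueError):
            realize_case_disposition("BOGUS", config, random.Random(0))

    def test_identical_seed_gives_byte_identical_files(self, config, tmp_path):
        outs = []
        for sub in ("a", "b"):
            d = tmp_path / sub
            d.mkdir()
            records, events, intended = generate_population(config)
            cfio.write_demographics(str(d / "demographics.tsv"), records)
            cfio.write_truth(str(d / "truth.tsv"), records)
            cfio.write_events(str(d / "events.tsv"), events)
            outs.append(d)
        for name in ("demographics.tsv", "truth.tsv", "events.tsv"):
            assert (outs[0] / name).read_bytes() == (outs[1] / name).read_bytes()

    def test_truth_round_trips_through_tsv(self, config, tmp_path):
        records, _, _ = generate_population(config)
        cfio.write_demographics(str(tmp_path / "d.tsv"), records)
        cfio.write_truth(str(tmp_path / "t.tsv"), records)
        loaded = cfio.read_patients(str(tmp_path / "d.tsv"), str(tmp_path / "t.tsv"))
        assert len(loaded) == len(records)
        for r in records:
            assert loaded[r.patient_id] == r


class TestRealizeCaseDisposition:
    @pytest.mark.parametrize("label", CASE_LABELS)
    def test_every_label_realizes_and_round_trips(self, config, label):
        rng = random.Random(42)
        for _ in range(25):
            record, events = realize_case_disposition(label, config, rng)
            record.validate()
            assert assess_case(record, config.criteria).label == expected_screen_label(
                label
            )
            # the event layer always qualifies, even when the truth does not
            assert evaluate_query(events, case_query()) == {record.patient_id}
            horizon = config.horizon
            assert all(horizon.contains(e.date) for e in events)

    def test_no_stone_label_still_has_stone_code(self, config):
        rng = random.Random(1)
        record, events = realize_case_disposition("NO_STONE", config, rng)
        assert not record.has_true_stone
        assert any(e.code.startswith("592") for e in events)


class TestControlStream:
    def _case(self, config, rng=None):
        rng = rng or random.Random(5)
        record, _ = realize_case_disposition("INCLUDED", config, rng)
        return record

    def test_candidates_match_case_and_pass_control_query(self, config):
        case = self._case(config)
        rng = random.Random(17)
        for record, events, label in generate_control_stream(case, config, rng):
            assert record.sex == case.sex
            assert abs((record.dob - case.dob).days) <= config.dob_tolerance_days
            assert evaluate_query(events, control_query()) == {record.patient_id}
            assert (
                assess_control(record, config.criteria, case.stone_dx_date).label
                == label
            )

    def test_pool_cap_bounds_stream_length(self, config):
        case = self._case(config)
        stream = list(generate_control_stream(case, config, random.Random(3)))
        assert len(stream) == config.control_pool_cap

    def test_degenerate_eligibility_yields_immediate_matches(self, config):
        import dataclasses

        cfg = dataclasses.replace(config, control_stream_eligibility=1.0)
        case = self._case(cfg)
        stream = generate_control_stream(case, cfg, random.Random(2))
        first_two = [next(stream) for _ in range(2)]
        assert [lab for _, _, lab in first_two] == ["ELIGIBLE", "ELIGIBLE"]

    def test_ineligibility_split_within_three_se(self, config):
        case = self._case(config)
        rng = random.Random(23)
        n = 6000
        labels = [
            lab
            for _, _, lab in generate_control_stream(case, config, rng, pool_cap=n)
        ]
        p_elig = config.control_stream_eligibility
        obs_elig = labels.count("ELIGIBLE") / n
        assert abs(obs_elig - p_elig) <= 3 * math.sqrt(p_elig * (1 - p_elig) / n)
        inel = [lab for lab in labels if lab != "ELIGIBLE"]
        for lab, p in config.control_ineligibility_split.items():
            obs = inel.count(lab) / len(inel)
            assert abs(obs - p) <= 3 * math.sqrt(p * (1 - p) / len(inel)), lab

    def test_case_without_index_date_rejected(self, config):
        record, _ = realize_case_disposition("NO_STONE", config, random.Random(0))
        with pytest.raises(ValueError):
            next(generate_control_stream(record, config, random.Random(0)))


class TestFixedMargins:
    def test_largest_remainder_reproduces_study_counts(self, config):
        counts = largest_remainder_counts(
            config.case_disposition_probs, 177, CASE_LABELS
        )
        assert counts == {
            "INCLUDED": 41,
            "NO_STONE": 28,
            "NO_GTUBE": 3,
            "AGE_RANGE": 42,
            "STUDY_PERIOD": 35,
            "ASYNCHRONOUS": 14,
            "INADEQUATE_DATA": 13,
            "NO_CONTROL": 1,
        }

    def test_largest_remainder_sums_to_n(self, config):
        for n in (0, 1, 10, 100, 177, 250):
            counts = largest_remainder_counts(
                config.case_disposition_probs, n, CASE_LABELS
            )
            assert sum(counts.values()) == n

    def test_fixed_margin_population_has_exact_counts(self, config):
        _, _, intended = generate_population(config, fixed_margins=True)
        from collections import Counter

        assert Counter(intended.values())["INCLUDED"] == 41
        assert Counter(intended.values())["NO_CONTROL"] == 1

    def test_fixed_control_allocation_totals(self, config):
        ids = [f"P{i:05d}" for i in range(41)]
        streams = allocate_fixed_control_streams(ids, config, random.Random(4))
        all_labels = [lab for seq in streams.values() for lab in seq]
        assert all_labels.count("ELIGIBLE") == 80  # 39*2 + 2*1
        assert all_labels.count("NO_GTUBE") == 31
        assert all_labels.count("ASYNCHRONOUS") == 82
        assert all_labels.count("INADEQUATE_DATA") == 293
        # full streams end on the final accepted control so every planned
        # ineligible chart gets reviewed
        n_short = sum(
            1 for seq in streams.values() if seq.count("ELIGIBLE") == 1
        )
        assert n_short == 2
        for seq in streams.values():
            if seq.count("ELIGIBLE") == config.match_ratio:
                assert seq[-1] == "ELIGIBLE"
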