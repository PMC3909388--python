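"""Chart-review screening: age rule, feed-window rule, disposition precedence."""
import datetime

import pytest
from hypothesis import given
from hypothesis import strategies as st

from cohortflow import (
    EligibilityCriteria,
    FeedRule,
    PatientRecord,
    age_at,
    assess_case,
    assess_control,
    feed_months_in_window,
)

CRIT = EligibilityCriteria()
DX = datetime.date(2008, 6, 15)


def record(**kw):
    base = dict(
        patient_id="P1",
        dob=datetime.date(1998, 3, 2),
        sex="F",
        has_true_stone=True,
        stone_dx_date=DX,
        has_true_gtube=True,
        gtube_placement_date=datetime.date(2005, 2, 10),
        feed_months=frozenset({(2007, 9), (2008, 1), (2008, 4), (2008, 6)}),
        nutrition_data_adequate=True,
    )
    base.update(kw)
    return PatientRecord(**base)


class TestAgeAt:
    @pytest.mark.parametrize(
        "dob, on, expected",
        [
            (datetime.date(2000, 6, 15), datetime.date(2021, 6, 14), 20),
            (datetime.date(2000, 6, 15), datetime.date(2021, 6, 15), 21),
            (datetime.date(2000, 6, 15), datetime.date(2000, 6, 15), 0),
            (datetime.date(2004, 2, 29), datetime.date(2007, 2, 28), 2),
            (datetime.date(2004, 2, 29), datetime.date(2007, 3, 1), 3),
        ],
    )
    def test_birthday_floor(self, dob, on, expected):
        assert age_at(dob, on) == expected

    def test_date_before_birth_rejected(self):
        with pytest.raises(ValueError):
            age_at(datetime.date(2000, 1, 2), datetime.date(2000, 1, 1))

    @given(
        dob=st.dates(datetime.date(1980, 1, 1), datetime.date(2012, 12, 31)),
        offset=st.integers(0, 15000),
    )
    def test_matches_anniversary_iteration_oracle(self, dob, offset):
        on = dob + datetime.timedelta(days=offset)

        def anniversary(k):
            try:
                return dob.replace(year=dob.year + k)
            except ValueError:  # Feb 29 -> Mar 1 in non-leap years
                return datetime.date(dob.year + k, 3, 1)

        k = 0
        while anniversary(k + 1) <= on:
            k += 1
        assert age_at(dob, on) == k


class TestFeedWindow:
    def test_minimal_satisfying_exposure(self):
        months = {(2009, 7), (2009, 8), (2009, 9)}
        assert feed_months_in_window(months, datetime.date(2010, 6, 15)) == 3

    def test_empty_set(self):
        assert feed_months_in_window(set(), DX) == 0

    def test_window_is_twelve_months_inclusive_of_index_month(self):
        idx = datetime.date(2010, 6, 15)
        assert feed_months_in_window({(2010, 6)}, idx) == 1  # index month counts
        assert feed_months_in_window({(2009, 7)}, idx) == 1  # oldest in-window month
        assert feed_months_in_window({(2009, 6)}, idx) == 0  # 13 months back
        assert feed_months_in_window({(2010, 7)}, idx) == 0  # after index month

    @given(
        months=st.sets(
            st.tuples(st.integers(2004, 2013), st.integers(1, 12)), max_size=30
        ),
        idx=st.dates(datetime.date(2005, 1, 1), datetime.date(2012, 12, 31)),
    )
    def test_matches_month_enumeration_oracle(self, months, idx):
        # walk the 12 calendar months backwards from the index month
        window = []
        y, m = idx.year, idx.month
        for _ in range(12):
            window.append((y, m))
            m -= 1
            if m == 0:
                y, m = y - 1, 12
        assert feed_months_in_window(months, idx) == len(set(months) & set(window))

    def test_adding_a_month_never_reduces_the_count(self):
        months = {(2008, 1), (2008, 3)}
        base = feed_months_in_window(months, DX)
        assert feed_months_in_window(months | {(2008, 5)}, DX) >= base


class TestAssessCase:
    def test_fully_valid_record_included(self):
        assert assess_case(record(), CRIT).label == "INCLUDED"

    @pytest.mark.parametrize(
        "kw, expected",
        [
            (dict(has_true_stone=False, stone_dx_date=None), "NO_STONE"),
            (
                dict(
                    has_true_gtube=False,
                    gtube_placement_date=None,
                    feed_months=frozenset(),
                ),
                "NO_GTUBE",
            ),
            (dict(stone_dx_date=datetime.date(2003, 5, 1)), "STUDY_PERIOD"),
            (dict(dob=datetime.date(2008, 1, 1)), "AGE_RANGE"),  # age 0 at dx
            (dict(dob=datetime.date(1980, 1, 1)), "AGE_RANGE"),  # age 28 at dx
            (
                dict(
                    gtube_placement_date=datetime.date(2009, 1, 1),
                    feed_months=frozenset({(2009, 1), (2009, 2), (2009, 3)}),
                ),
                "ASYNCHRONOUS",  # stone predates placement
            ),
            (dict(feed_months=frozenset({(2008, 1), (2008, 2)})), "ASYNCHRONOUS"),
            (dict(nutrition_data_adequate=False), "INADEQUATE_DATA"),
        ],
    )
    def test_single_rule_failures(self, kw, expected):
        assert assess_case(record(**kw), CRIT).label == expected

    def test_precedence_first_failing_rule_wins(self):
        # unverifiable stone beats unverifiable G-tube
        r = record(
            has_true_stone=False,
            stone_dx_date=None,
            has_true_gtube=False,
            gtube_placement_date=None,
            feed_months=frozenset(),
        )
        assert assess_case(r, CRIT).label == "NO_STONE"
        # out-of-period diagnosis beats out-of-range age
        r = record(stone_dx_date=datetime.date(2003, 5, 1), dob=datetime.date(2003, 1, 1))
        assert assess_case(r, CRIT).label == "STUDY_PERIOD"

    def test_age_bounds_inclusive(self):
        assert assess_case(record(dob=DX.replace(year=DX.year - 1)), CRIT).label == "INCLUDED"
        assert assess_case(record(dob=DX.replace(year=DX.year - 21)), CRIT).label == "INCLUDED"
        # one day older than exactly 22 years -> age 21, still in range
        assert (
            assess_case(
                record(dob=DX.replace(year=DX.year - 22) + datetime.timedelta(days=1)),
                CRIT,
            ).label
            == "INCLUDED"
        )
        assert (
            assess_case(record(dob=DX.replace(year=DX.year - 22)), CRIT).label
            == "AGE_RANGE"
        )

    def test_flag_without_date_is_input_error(self):
        r = record()
        r.stone_dx_date = None  # corrupt after construction
        with pytest.raises(ValueError):
            assess_case(r, CRIT)

    def test_determinism(self):
        r = record(nutrition_data_adequate=False)
        assert assess_case(r, CRIT) == assess_case(r, CRIT)


class TestAssessControl:
    def ctrl(self, **kw):
        base = dict(
            has_true_stone=False,
            stone_dx_date=None,
            patient_id="C1",
        )
        base.update(kw)
        return record(**base)

    def test_eligible_when_feeds_cover_window(self):
        months = frozenset((2007, m) for m in range(7, 13)) | frozenset(
            (2008, m) for m in range(1, 7)
        )
        r = self.ctrl(feed_months=months, gtube_placement_date=datetime.date(2006, 1, 1))
        assert assess_control(r, CRIT, DX).label == "ELIGIBLE"

    def test_no_gtube(self):
        r = self.ctrl(
            has_true_gtube=False, gtube_placement_date=None, feed_months=frozenset()
        )
        assert assess_control(r, CRIT, DX).label == "NO_GTUBE"

    def test_placement_on_or_after_index_is_asynchronous(self):
        r = self.ctrl(
            gtube_placement_date=DX, feed_months=frozenset({(2008, 6), (2008, 7), (2008, 8)})
        )
        assert assess_control(r, CRIT, DX).label == "ASYNCHRONOUS"

    def test_underexposure_is_asynchronous(self):
        r = self.ctrl(feed_months=frozenset({(2008, 1), (2008, 2)}))
        assert assess_control(r, CRIT, DX).label == "ASYNCHRONOUS"

    def test_inadequate_data_checked_after_feed_rule(self):
        r = self.ctrl(nutrition_data_adequate=False)
        assert assess_control(r, CRIT, DX).label == "INADEQUATE_DATA"
        r = self.ctrl(
            nutrition_data_adequate=False, feed_months=frozenset({(2008, 1)})
        )
        assert assess_control(r, CRIT, DX).label == "ASYNCHRONOUS"

    def test_missing_index_date_is_error(self):
        with pytest.raises(ValueError):
            assess_control(self.ctrl(), CRIT, None)

    def test_feed_rule_monotone_adding_months_never_excludes(self):
        months = frozenset({(2008, 1), (2008, 2)})
        r = self.ctrl(feed_months=months)
        assert assess_control(r, CRIT, DX).label == "ASYNCHRONOUS"
        r2 = self.ctrl(feed_months=months | {(2008, 5)})
        assert assess_control(r2, CRIT, DX).label == "ELIGIBLE"
        r3 = self.ctrl(feed_months=months | {(2008, 5), (2008, 6)})
        assert assess_control(r3, CRIT, DX).label == "ELIGIBLE"


class TestFeedRuleConfig:
    def test_custom_rule_applied(self):
        crit = EligibilityCriteria(feed_rule=FeedRule(min_months=6, window_months=12))
        r = record()  # 4 in-window feed months
        assert assess_case(r, crit).label == "ASYNCHRONOUS"
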