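import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pgxoutcomes.outcomes import (
    OutcomeParams,
    antipsychotic_overlap,
    build_outcome_table,
    build_windows,
    detect_side_effects,
    detect_switch,
    discontinuation_def1,
    discontinuation_def2,
    duration_count,
    duration_weeks,
)

from _oracles import (
    naive_disc1,
    naive_disc2,
    naive_side_effects,
    naive_switch,
    naive_weeks,
    naive_windows,
)
from conftest import make_timeline

ESC = "ssri_escitalopram"
CIT = "ssri_citalopram"
SER = "ssri_sertraline"
PARAMS = OutcomeParams()


class TestWindows:
    @pytest.mark.parametrize(
        "days,expected",
        [
            ([0, 60, 155], [(0, 60, 2), (155, 155, 1)]),
            ([0, 89], [(0, 89, 2)]),
            ([0, 90], [(0, 0, 1), (90, 90, 1)]),  # exactly 90 starts anew
            ([5], [(5, 5, 1)]),
            ([], []),
        ],
    )
    def test_examples(self, days, expected):
        assert build_windows(np.array(days), 90) == expected

    @settings(derandomize=True, max_examples=200)
    @given(st.lists(st.integers(0, 700), max_size=12), st.sampled_from([30, 90, 180]))
    def test_matches_bruteforce_split(self, days, gap):
        days = np.unique(np.array(days, dtype=np.int64))
        assert build_windows(days, gap) == naive_windows(days.tolist(), gap)

    def test_weeks_examples(self):
        assert duration_weeks(build_windows(np.array([0, 60, 155]))) == pytest.approx(60 / 7)
        assert duration_weeks(build_windows(np.array([42]))) == 0.0

    def test_weeks_translation_invariant(self):
        days = np.array([0, 30, 200, 230, 400])
        for k in (-500, 17, 10000):
            assert duration_weeks(build_windows(days + k)) == duration_weeks(
                build_windows(days)
            )


class TestDurationCount:
    def test_same_day_issues_counted_once(self):
        tl = make_timeline(rx=[(0, ESC), (0, ESC), (30, ESC), (60, ESC), (90, ESC)])
        assert duration_count(tl, ESC) == 4

    def test_count_at_least_windows(self):
        tl = make_timeline(rx=[(0, ESC), (200, ESC), (500, ESC)])
        assert duration_count(tl, ESC) >= len(build_windows(tl.index_days(ESC)))


class TestSwitch:
    def test_hand_traced_case_at_all_windows(self):
        """Index issues at 0/28/56, another agent first issued at day 84:
        a switch 28 days after the last index issue."""
        tl = make_timeline(rx=[(0, ESC), (28, ESC), (56, ESC), (84, SER)])
        for w in (30, 60, 90):
            assert detect_switch(tl, ESC, w) == "case"

    def test_three_consecutive_no_switch_is_control(self):
        tl = make_timeline(rx=[(0, ESC), (28, ESC), (56, ESC)])
        for w in (30, 60, 90):
            assert detect_switch(tl, ESC, w) == "control"

    def test_late_switch_excludes_from_both_arms(self):
        """A switch 94 days out is outside every window but still
        disqualifies the person as a control."""
        tl = make_timeline(rx=[(0, ESC), (28, ESC), (56, ESC), (150, SER)])
        for w in (30, 60, 90):
            assert detect_switch(tl, ESC, w) == "excluded"

    def test_same_day_switch_counts_as_within_window(self):
        tl = make_timeline(rx=[(0, ESC), (28, ESC), (56, ESC), (56, SER)])
        assert detect_switch(tl, ESC, 30) == "case"

    def test_fewer_than_three_issues_no_switch_excluded(self):
        tl = make_timeline(rx=[(0, ESC), (28, ESC)])
        assert detect_switch(tl, ESC, 30) == "excluded"

    def test_heavy_prescribing_around_switch_fails_tolerance(self):
        # two index issues within 30 days before the switch date
        tl = make_timeline(rx=[(0, ESC), (14, ESC), (28, ESC), (40, SER)])
        assert detect_switch(tl, ESC, 30) == "excluded"
        assert detect_switch(tl, ESC, 60) == "excluded"
        # the 90-day window tolerates 2
        assert detect_switch(tl, ESC, 90) == "case"

    def test_case_at_30_implies_case_at_wider_windows(self):
        tl = make_timeline(rx=[(0, ESC), (28, ESC), (56, ESC), (70, SER)])
        statuses = [detect_switch(tl, ESC, w) for w in (30, 60, 90)]
        assert statuses == ["case", "case", "case"]


class TestDiscontinuation:
    def test_single_issue_then_nothing_is_def1_case(self):
        tl = make_timeline(rx=[(0, CIT)], record_end=200)
        assert discontinuation_def1(tl, CIT) == "case"

    def test_censored_single_issue_excluded(self):
        tl = make_timeline(rx=[(0, CIT)], record_end=90)
        assert discontinuation_def1(tl, CIT) == "excluded"

    def test_two_issues_not_def1_case(self):
        tl = make_timeline(rx=[(0, CIT), (21, CIT)], record_end=400)
        assert discontinuation_def1(tl, CIT) == "excluded"  # < 3 issues, no switch
        # but a short period counts under the window definition
        assert discontinuation_def2(tl, CIT) == "case"

    def test_short_window_then_stop_is_def2_case(self):
        tl = make_timeline(rx=[(0, CIT), (21, CIT), (42, CIT)], record_end=242)
        assert discontinuation_def2(tl, CIT) == "case"

    def test_eight_week_span_not_case(self):
        tl = make_timeline(rx=[(0, CIT), (35, CIT), (70, CIT)], record_end=400)
        assert discontinuation_def2(tl, CIT) == "control"
        # strict boundary: span exactly 56 days is not under 8 weeks
        tl = make_timeline(rx=[(0, CIT), (28, CIT), (56, CIT)], record_end=400)
        assert discontinuation_def2(tl, CIT) == "control"

    def test_followed_by_other_agent_is_not_stoppage(self):
        tl = make_timeline(rx=[(0, CIT), (21, CIT), (42, CIT), (60, SER)], record_end=400)
        assert discontinuation_def2(tl, CIT) == "excluded"
        tl1 = make_timeline(rx=[(0, CIT), (60, SER)], record_end=400)
        assert discontinuation_def1(tl1, CIT) == "excluded"


class TestSideEffects:
    def test_event_shortly_after_first_issue(self):
        tl = make_timeline(
            rx=[(0, ESC), (28, ESC)], events=[(10, "R090.", True)], record_start=-60
        )
        assert detect_side_effects(tl, ESC, 30) == "case"
        assert detect_side_effects(tl, ESC, 60) == "case"

    def test_window_membership(self):
        tl = make_timeline(
            rx=[(0, ESC)], events=[(45, "R090.", True)], record_start=-60, record_end=400
        )
        assert detect_side_effects(tl, ESC, 30) == "control"
        assert detect_side_effects(tl, ESC, 60) == "case"

    def test_prior_occurrence_of_same_code_blocks_case(self):
        tl = make_timeline(
            rx=[(0, ESC)],
            events=[(-5, "R090.", True), (10, "R090.", True)],
            record_start=-60,
            record_end=400,
        )
        assert detect_side_effects(tl, ESC, 30) == "control"

    def test_different_prior_code_does_not_block(self):
        tl = make_timeline(
            rx=[(0, ESC)],
            events=[(-5, "1B1B.", True), (10, "R090.", True)],
            record_start=-60,
            record_end=400,
        )
        assert detect_side_effects(tl, ESC, 30) == "case"

    def test_insufficient_coverage_excluded(self):
        tl = make_timeline(rx=[(0, ESC)], events=[(10, "R090.", True)], record_start=-10)
        assert detect_side_effects(tl, ESC, 30) == "excluded"
        tl = make_timeline(rx=[(0, ESC)], record_start=-60, record_end=40)
        assert detect_side_effects(tl, ESC, 60) == "excluded"

    def test_unlisted_event_is_not_a_side_effect(self):
        tl = make_timeline(
            rx=[(0, ESC)], events=[(10, "4K22.", False)], record_start=-60, record_end=400
        )
        assert detect_side_effects(tl, ESC, 30) == "control"


class TestAntipsychoticOverlap:
    @pytest.mark.parametrize(
        "ap_day,expected", [(30, True), (0, True), (60, True), (-10, False), (70, False)]
    )
    def test_envelope(self, ap_day, expected):
        tl = make_timeline(rx=[(0, ESC), (60, ESC), (ap_day, "antipsychotic")])
        assert antipsychotic_overlap(tl, ESC) is expected

    def test_no_antipsychotics(self):
        tl = make_timeline(rx=[(0, ESC), (60, ESC)])
        assert antipsychotic_overlap(tl, ESC) is False


# random-timeline strategies for oracle equivalence
drug_class = st.sampled_from([ESC, CIT, SER, "other_antidepressant", "antipsychotic", "other"])
rx_stream = st.lists(st.tuples(st.integers(0, 600), drug_class), min_size=1, max_size=12)
event_stream = st.lists(
    st.tuples(
        st.integers(-80, 400),
        st.sampled_from(["R090.", "1B1B.", "R0051"]),
        st.booleans(),
    ),
    max_size=6,
)


class TestOracleEquivalence:
    """On random small timelines every classifier agrees with a naive
    loop-based restatement of its rules."""

    @settings(derandomize=True, max_examples=300)
    @given(rx=rx_stream, record_end=st.integers(300, 900))
    def test_switch_disc_and_duration(self, rx, record_end):
        tl = make_timeline(rx=rx, record_end=record_end)
        rx_set = sorted(set(rx))
        for ssri in (ESC, CIT, SER):
            for w in (30, 60, 90):
                assert detect_switch(tl, ssri, w) == naive_switch(
                    rx_set, ssri, w, PARAMS.switch_tolerances[w]
                ), (rx_set, ssri, w)
            if tl.index_days(ssri).size:
                assert discontinuation_def1(tl, ssri) == naive_disc1(rx_set, ssri, record_end)
                assert discontinuation_def2(tl, ssri) == naive_disc2(rx_set, ssri, record_end)
                assert duration_weeks(
                    build_windows(tl.index_days(ssri))
                ) == pytest.approx(naive_weeks([d for d, c in rx_set if c == ssri]))

    @settings(derandomize=True, max_examples=200)
    @given(rx=rx_stream, events=event_stream, post=st.sampled_from([30, 60]))
    def test_side_effects(self, rx, events, post):
        tl = make_timeline(rx=rx, events=events, record_start=-100, record_end=900)
        for ssri in (ESC, CIT):
            if tl.index_days(ssri).size:
                assert detect_side_effects(tl, ssri, post) == naive_side_effects(
                    sorted(set(rx)), sorted(set(events)), ssri, post, -100, 900
                )

    @settings(derandomize=True, max_examples=100)
    @given(rx=rx_stream, shift=st.integers(-300, 3000))
    def test_translation_invariance(self, rx, shift):
        tl = make_timeline(rx=rx, record_end=900)
        tl2 = tl.shifted(shift)
        for ssri in (ESC, CIT, SER):
            for w in (30, 60, 90):
                assert detect_switch(tl, ssri, w) == detect_switch(tl2, ssri, w)
            assert discontinuation_def2(tl, ssri) == discontinuation_def2(tl2, ssri)
            assert duration_weeks(build_windows(tl.index_days(ssri))) == duration_weeks(
                build_windows(tl2.index_days(ssri))
            )


class TestOutcomeTable:
    def _cohort(self):
        timelines = [
            make_timeline(person_id="p1", rx=[(0, ESC), (28, ESC), (56, ESC)], record_end=400),
            make_timeline(
                person_id="p2", rx=[(0, CIT), (30, CIT), (60, CIT), (300, SER), (330, SER), (360, SER)],
                record_end=700,
            ),
            make_timeline(person_id="p3", rx=[(0, SER)], record_end=300),
        ]
        cov = pd.DataFrame(
            {
                "person_id": ["p1", "p2", "p3"],
                "sex": [1, 0, 1],
                "year_of_birth": [1950, 1960, 1945],
                "batch": ["b1", "b2", "b1"],
                "broad_depression": [1, 1, 0],
            }
        )
        pheno = pd.DataFrame(
            {
                "person_id": ["p1", "p2", "p3"],
                "phenotype": ["poor", "normal", "fast"],
                "activity_score": [0.0, 2.0, 3.0],
                "included": [True, True, True],
            }
        )
        return timelines, cov, pheno

    def test_one_row_per_person_ssri(self):
        timelines, cov, pheno = self._cohort()
        table = build_outcome_table(timelines, cov, pheno)
        assert len(table) == 4  # p2 contributes two rows
        assert set(table.loc[table["person_id"] == "p2", "ssri"]) == {CIT, SER}

    def test_statuses_match_hand_computed_reference(self):
        timelines, cov, pheno = self._cohort()
        table = build_outcome_table(timelines, cov, pheno).set_index(["person_id", "ssri"])
        # p1: 3 issues, nothing else -> control everywhere, count 3, 8 weeks
        assert table.loc[("p1", ESC), "switch_60"] == "control"
        assert table.loc[("p1", ESC), "disc_def2"] == "control"
        assert table.loc[("p1", ESC), "duration_count"] == 3
        assert table.loc[("p1", ESC), "duration_weeks"] == pytest.approx(8.0)
        # p2/citalopram: sertraline first issued 240 days after the last
        # citalopram issue -> outside all windows, and no control status
        assert table.loc[("p2", CIT), "switch_30"] == "excluded"
        assert table.loc[("p2", CIT), "disc_def2"] == "excluded"
        # p2/sertraline: three consecutive issues, nothing after
        assert table.loc[("p2", SER), "switch_90"] == "control"
        # p3: single issue then nothing, 300 days of record
        assert table.loc[("p3", SER), "disc_def1"] == "case"
        assert table.loc[("p3", SER), "disc_def2"] == "case"
        assert table.loc[("p3", SER), "duration_weeks"] == 0.0

    def test_missing_covariates_skipped(self):
        timelines, cov, pheno = self._cohort()
        table = build_outcome_table(timelines, cov[cov["person_id"] != "p3"], pheno)
        assert "p3" not in set(table["person_id"])
        assert table.attrs["n_missing_covariates"] == 1

    def test_age_at_first_rx(self):
        timelines, cov, pheno = self._cohort()
        table = build_outcome_table(timelines, cov, pheno)
        p1 = table[table["person_id"] == "p1"].iloc[0]
        assert p1["age_at_first_rx"] == p1["first_rx_date"].year - 1950
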