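"""Coverage, gap, punctuality, and self-report indicator arithmetic.

The frozen expected values for coverage and gap runs were computed with
the per-day boolean possession grid in conftest (``daygrid_coverage``)
and are cross-checked against it here on randomized histories.
"""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from adhind.config import ObservationWindow, SummaryConfig
from adhind.indicators import (coverage, facility_indicators, punctuality,
                               self_report)
from conftest import WINDOW_START, daygrid_coverage, events_frame, \
    random_patient_events


def cfg(**kw):
    return SummaryConfig(**kw)


class TestCoverage:
    def test_full_cover_single_fill(self, window):
        cov = coverage(events_frame([0], [180]), window, cfg())
        assert cov.pct_days_covered == 100.0
        assert cov.covered_days == 180
        assert cov.max_uncovered_run_days == 0
        assert cov.has_gap_ge_threshold is False

    def test_monthly_fills_with_short_gaps_stockpile(self, window):
        # 30-day fills at 0, 30, 70, 100, 130, 160: one 10-day hole at 60,
        # final fill truncated at the window edge
        cov = coverage(events_frame([0, 30, 70, 100, 130, 160], [30] * 6),
                       window, cfg(carryover_policy="stockpile"))
        assert cov.covered_days == 170
        assert cov.pct_days_covered == pytest.approx(94.4, abs=0.05)
        assert cov.max_uncovered_run_days == 10
        assert cov.has_gap_ge_threshold is False

    def test_early_refill_carryover_policies(self, window):
        events = events_frame([0, 25], [30, 30])
        stock = coverage(events, window, cfg(carryover_policy="stockpile"))
        trunc = coverage(events, window, cfg(carryover_policy="truncate"))
        assert stock.covered_days == 60   # second fill banked to days 30-59
        assert trunc.covered_days == 55   # union of [0,30) and [25,55)

    @pytest.mark.parametrize("gap_scope,expected_run", [
        ("include_trailing", 85),    # runs: days 30-64 (35) and 95-179 (85)
        ("between_fills_only", 35),  # trailing run after day 65 fill ignored
    ])
    def test_gap_scope_controls_trailing_run(self, window, gap_scope,
                                             expected_run):
        cov = coverage(events_frame([0, 65], [30, 30]), window,
                       cfg(gap_scope=gap_scope))
        assert cov.max_uncovered_run_days == expected_run
        assert cov.has_gap_ge_threshold is True

    def test_continuous_refills_no_gap(self, window):
        cov = coverage(events_frame([0, 30, 60, 90, 120, 150], [30] * 6),
                       window, cfg())
        assert cov.max_uncovered_run_days == 0
        assert cov.has_gap_ge_threshold is False

    def test_zero_fills(self, window):
        empty = events_frame([], [])
        trail = coverage(empty, window, cfg(gap_scope="include_trailing"))
        assert trail.covered_days == 0
        assert trail.max_uncovered_run_days == 180
        assert trail.has_gap_ge_threshold is True
        between = coverage(empty, window, cfg(gap_scope="between_fills_only"))
        assert between.max_uncovered_run_days is None
        assert between.has_gap_ge_threshold is None

    def test_out_of_window_events_ignored_no_spill(self, window):
        # a 60-day fill the day before the window must not spill in
        cov = coverage(events_frame([-1, 40], [60, 30]), window, cfg())
        assert cov.covered_days == 30
        assert cov.n_fills_in_window == 1

    @pytest.mark.parametrize("policy", ["stockpile", "truncate"])
    @pytest.mark.parametrize("gap_scope", ["include_trailing",
                                           "between_fills_only"])
    def test_matches_daygrid_oracle_randomized(self, window, policy, gap_scope):
        rng = np.random.default_rng(42)
        config = cfg(carryover_policy=policy, gap_scope=gap_scope)
        for _ in range(300):
            days, supplies = random_patient_events(rng)
            cov = coverage(events_frame(days, supplies), window, config)
            exp_cov, exp_run = daygrid_coverage(days, supplies, 180,
                                                policy, gap_scope)
            assert cov.covered_days == exp_cov
            assert cov.max_uncovered_run_days == exp_run

    @given(st.lists(st.tuples(st.integers(0, 179), st.integers(1, 60)),
                    min_size=0, max_size=8),
           st.tuples(st.integers(0, 179), st.integers(1, 60)))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_adding_a_fill_is_monotone(self, fills, extra):
        """More medicine never lowers coverage; a fill at or after the
        first existing fill never lengthens the worst gap.

        (An *earlier* fill can lengthen the reported run because the gap
        search region is anchored at the first fill day, so adding one
        extends the region backward.)
        """
        window = ObservationWindow(WINDOW_START, 180)
        days = [d for d, _ in fills]
        supplies = [s for _, s in fills]
        base = coverage(events_frame(days, supplies), window, cfg())
        more = coverage(events_frame(days + [extra[0]], supplies + [extra[1]]),
                        window, cfg())
        assert more.covered_days >= base.covered_days
        if not days or extra[0] >= min(days):
            assert more.max_uncovered_run_days <= base.max_uncovered_run_days

    @given(st.lists(st.tuples(st.integers(0, 179), st.integers(1, 60)),
                    min_size=0, max_size=8))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_gap_implies_coverage_bound(self, fills):
        """A >=30-day in-window gap caps coverage at 100*(W-G)/W."""
        window = ObservationWindow(WINDOW_START, 180)
        cov = coverage(events_frame([d for d, _ in fills],
                                    [s for _, s in fills]), window, cfg())
        if cov.has_gap_ge_threshold:
            assert cov.pct_days_covered <= 100.0 * (180 - 30) / 180 + 1e-9


class TestSelfReport:
    @pytest.mark.parametrize("prescribed,missed,pct,perfect", [
        (6, 0, 100.0, True),
        (6, 1, 83.33, False),
        (6, 6, 0.0, False),
    ])
    def test_examples(self, prescribed, missed, pct, perfect):
        got_pct, got_perfect = self_report(prescribed, missed)
        assert got_pct == pytest.approx(pct, abs=0.005)
        assert got_perfect is perfect

    def test_zero_prescribed_undefined(self):
        assert self_report(0, 0) is None


class TestPunctuality:
    @pytest.mark.parametrize("late,flags", [
        (-5, (True, True, True)),
        (0, (True, True, True)),
        (3, (False, True, True)),
        (4, (False, False, True)),
        (30, (False, False, True)),
        (31, (False, False, False)),
    ])
    def test_day_windows(self, late, flags):
        sched = WINDOW_START
        attended = sched + pd.Timedelta(days=late).to_pytimedelta()
        out = punctuality("p1", sched, attended)
        assert (out.attended_on_time, out.attended_within_3,
                out.attended_within_30) == flags
        assert out.days_late == late
        # nesting: on_time => within_3 => within_30
        assert (not out.attended_on_time) or out.attended_within_3
        assert (not out.attended_within_3) or out.attended_within_30

    def test_never_attended_fails_all_windows(self):
        out = punctuality("p1", WINDOW_START, None)
        assert out.days_late is None
        assert not (out.attended_on_time or out.attended_within_3
                    or out.attended_within_30)


class TestFacilityRow:
    def test_gap_percentage_by_hand(self, window, default_config):
        # 10 patients, 3 with a >=30-day gap (single fill at day 0 leaves
        # a 150-day trailing run); the rest refill continuously
        rows = []
        for i in range(10):
            days = [0] if i < 3 else [0, 30, 60, 90, 120, 150]
            events = events_frame(days, [30] * len(days),
                                  patient_id=f"p{i}")
            cov = coverage(events, window, default_config)
            rows.append({"patient_id": f"p{i}", "facility_id": "f1",
                         "in_treatment_at_end": True,
                         "pct_days_covered": cov.pct_days_covered,
                         "has_gap_ge_threshold": cov.has_gap_ge_threshold})
        cov_rows = pd.DataFrame(rows)
        row = facility_indicators("f1", "Kenya", cov_rows,
                                  pd.DataFrame(columns=["attended_on_time"]),
                                  pd.DataFrame(columns=["perfect"]))
        assert row["pct_patients_gap_ge_30"] == pytest.approx(30.0)
        assert row["n_dispensing_patients"] == 10
        assert np.isnan(row["pct_attended_on_time"])  # no appointments

    def test_attendance_percentages_by_enumeration(self):
        punct = pd.DataFrame({
            "days_late": [-1, 0, 3, 40],
            "attended_on_time": [True, True, False, False],
            "attended_within_3": [True, True, True, False],
            "attended_within_30": [True, True, True, False],
        })
        row = facility_indicators(
            "f1", "Kenya",
            pd.DataFrame(columns=["pct_days_covered", "has_gap_ge_threshold",
                                  "in_treatment_at_end"]),
            punct, pd.DataFrame(columns=["perfect"]))
        assert row["pct_attended_on_time"] == pytest.approx(50.0)
        assert row["pct_attended_within_3"] == pytest.approx(75.0)
        assert row["pct_attended_within_30"] == pytest.approx(75.0)
        assert np.isnan(row["mean_pct_days_covered"])  # no dispensing data
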