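"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately use different algorithms from the package:
coverage is checked against a per-day boolean possession grid, and the
facility gap indicator against a direct Monte-Carlo renewal simulation
driven by the stdlib ``random`` module.
"""

from __future__ import annotations

import math
import random
from datetime import date

import numpy as np
import pandas as pd
import pytest

from adhind.config import ObservationWindow, SummaryConfig

WINDOW_START = date(2020, 1, 1)


def daygrid_coverage(fill_days, supplies, window_days, policy,
                     gap_scope, gap_threshold=30):
    """Brute-force day-by-day coverage: mark each day covered/uncovered.

    Stockpile walks the window one day at a time carrying a pill stock;
    truncate marks each fill's literal interval. Returns
    ``(covered_days, max_uncovered_run or None)``.
    """
    fills = sorted(zip((int(d) for d in fill_days), (int(s) for s in supplies)))
    fills = [(d, s) for d, s in fills if 0 <= d < window_days]
    covered = np.zeros(window_days, dtype=bool)
    if policy == "stockpile":
        stock = 0
        supply_at = {}
        for d, s in fills:
            supply_at[d] = supply_at.get(d, 0) + s
        for day in range(window_days):
            stock += supply_at.get(day, 0)
            if stock > 0:
                covered[day] = True
                stock -= 1
    else:
        for d, s in fills:
            covered[d:min(d + s, window_days)] = True

    n_covered = int(covered.sum())
    if not fills:
        run = window_days if gap_scope == "include_trailing" else None
        return 0, run
    first = fills[0][0]
    last = fills[-1][0]
    end = window_days if gap_scope == "include_trailing" else last
    run = best = 0
    for day in range(first, end):
        run = 0 if covered[day] else run + 1
        best = max(best, run)
    return n_covered, best


def events_frame(fill_days, supplies, patient_id="p1", facility_id="f1",
                 start=WINDOW_START):
    """Dispensing DataFrame from integer day offsets."""
    from datetime import timedelta
    return pd.DataFrame({
        "patient_id": patient_id,
        "facility_id": facility_id,
        "dispense_date": [start + timedelta(days=int(d)) for d in fill_days],
        "days_supplied": list(int(s) for s in supplies),
    })


def random_patient_events(rng: np.random.Generator, window_days=180):
    """A randomized dispensing history for oracle-equivalence checks."""
    n = int(rng.integers(0, 9))
    days = sorted(rng.integers(0, window_days, size=n).tolist())
    supplies = rng.integers(1, 61, size=n).tolist()
    return days, supplies


def mc_gap_oracle(p_on_time, p_long_gap, short_delay_mean_days,
                  long_gap_min_days, monthly_dropout_hazard,
                  n_patients=100_000, window_days=180, refill_interval=30,
                  appointment_lead=28, gap_threshold=30, seed=12345):
    """Direct Monte-Carlo estimate of P(max uncovered run >= threshold).

    Simulates the same refill mixture as the generator — on-time at the
    appointment lead, geometric short delays past the scheduled day, long
    gaps past supply exhaustion, absorbing dropout — but as an
    independent renewal walk over continuous stockpile coverage, using
    the stdlib RNG. Returns (gap_probability, mean_pct_days_covered).
    """
    rnd = random.Random(seed)
    hazard = 1.0 - (1.0 - monthly_dropout_hazard) ** (refill_interval / 30.0)
    p_short = min(1.0, 1.0 / short_delay_mean_days)
    log1m_short = math.log(1.0 - p_short) if p_short < 1.0 else None
    log1m_long = math.log(0.9)

    def geom(log1m):  # >= 1, mean 1/p
        if log1m is None:
            return 1
        return int(math.log(1.0 - rnd.random()) / log1m) + 1

    n_gap = 0
    total_covered = 0.0
    W = window_days
    for _ in range(n_patients):
        t = 0
        cov_end = 0  # end of continuous possession (stockpile banking)
        max_run = 0
        uncovered = 0
        while True:
            start = max(t, cov_end)
            cov_end = start + refill_interval
            if rnd.random() < hazard:
                break
            u = rnd.random()
            if u < p_on_time:
                nxt = t + appointment_lead
            elif u < p_on_time + p_long_gap:
                nxt = t + refill_interval + long_gap_min_days + geom(log1m_long) - 1
            else:
                nxt = t + appointment_lead + geom(log1m_short)
            if nxt >= W:
                break
            run = max(0, nxt - cov_end)
            uncovered += run
            max_run = max(max_run, run)
            t = nxt
        trailing = max(0, W - min(cov_end, W))
        uncovered += trailing
        max_run = max(max_run, trailing)
        if max_run >= gap_threshold:
            n_gap += 1
        total_covered += 100.0 * (W - uncovered) / W
    return n_gap / n_patients, total_covered / n_patients


@pytest.fixture(scope="session")
def default_config():
    return SummaryConfig()


@pytest.fixture(scope="session")
def window():
    return ObservationWindow(WINDOW_START, 180)


@pytest.fixture(scope="session")
def small_scenario_tables():
    """A 12-facility scenario shared across aggregation tests."""
    from adhind.simulate import generate_scenario, study_like_scenario
    config = study_like_scenario(seed=7, n_facilities=12,
                                 patients_per_facility=60,
                                 n_without_dispensing=2)
    return generate_scenario(config)
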