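"""Per-patient and per-facility adherence and attendance indicators.

The indicator set covers three routine data sources:

* **Dispensing records** — proportion of days covered (PDC) by dispensed
  medicine over a fixed retrospective window, and detection of treatment
  gaps (runs of >= G consecutive uncovered days).
* **Appointment logs** — punctuality of clinic attendance relative to the
  scheduled date (on or before; within 3 days; within 30 days).
* **Exit interviews** — self-reported doses missed over the previous
  3 days (percentage of doses taken; perfect adherence flag).

Coverage is computed with interval arithmetic on integer day offsets; all
intervals are half-open ``[start, end)``. Two carryover policies are
supported:

``stockpile``
    Supply from an early refill is banked: each fill's supply starts at
    ``max(fill day, exhaustion day of all prior supply)``. This treats
    dispensed days of medicine as a possession quantity.
``truncate``
    Each fill covers ``[fill day, fill day + days_supplied)`` and overlaps
    are collapsed by set union; early-refill surplus is discarded.

Supply from fills dated before the observation window never spills into
it: the window is anchored at an attended (fill) day, and the indicator is
a function of in-window data only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import ObservationWindow, SummaryConfig
from .io import INDICATOR_COLUMNS

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PatientCoverage:
    """Dispensing-based coverage summary for one patient.

    ``max_uncovered_run_days`` and ``has_gap_ge_threshold`` are ``None``
    when undefined (zero in-window fills under the ``between_fills_only``
    gap scope).
    """

    patient_id: str
    covered_days: int
    pct_days_covered: float
    max_uncovered_run_days: int | None
    has_gap_ge_threshold: bool | None
    n_fills_in_window: int


@dataclass(frozen=True)
class PunctualityOutcome:
    """Lateness of one attended (or missed) appointment.

    ``days_late`` is negative for early attendance and ``None`` when the
    appointment was never attended; a never-attended appointment fails
    every punctuality window.
    """

    patient_id: str
    scheduled_date: object
    days_late: int | None
    attended_on_time: bool
    attended_within_3: bool
    attended_within_30: bool


def _merged_covered_intervals(fill_days: np.ndarray, supplies: np.ndarray,
                              window_days: int, policy: str) -> list[tuple[int, int]]:
    """Merged half-open covered intervals within [0, window_days).

    ``fill_days`` must be sorted ascending and lie inside the window.
    """
    intervals: list[tuple[int, int]] = []
    if policy == "stockpile":
        cur_end = -1
        for day, supply in zip(fill_days, supplies):
            start = max(int(day), cur_end)
            cur_end = start + int(supply)
            intervals.append((start, cur_end))
    elif policy == "truncate":
        for day, supply in zip(fill_days, supplies):
            intervals.append((int(day), int(day) + int(supply)))
        intervals.sort()
    else:  # pragma: no cover - guarded by SummaryConfig
        raise ValueError(f"unknown carryover policy {policy!r}")

    merged: list[tuple[int, int]] = []
    for start, end in intervals:
        end = min(end, window_days)
        if end <= start:
            continue
        if merged and start <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


def coverage(events: pd.DataFrame, window: ObservationWindow,
             config: SummaryConfig | None = None,
             patient_id: str | None = None) -> PatientCoverage:
    """Coverage and gap summary for one patient's dispensing events.

    Events dated outside the window are ignored (with a debug note). A
    patient with zero in-window fills has ``covered_days = 0`` and — under
    the ``include_trailing`` gap scope — a maximal uncovered run equal to
    the whole window.

    Parameters
    ----------
    events : DataFrame
        One patient's rows with ``dispense_date`` and ``days_supplied``.
    window : ObservationWindow
        The patient's retrospective window, anchored at their index visit.
    config : SummaryConfig, optional
        Supplies the carryover policy, gap scope, and gap threshold.
    """
    config = config or SummaryConfig()
    if patient_id is None:
        patient_id = str(events["patient_id"].iloc[0]) if len(events) else ""
    offsets = np.array([window.day_offset(d) for d in events["dispense_date"]],
                       dtype=int)
    supplies = events["days_supplied"].to_numpy(dtype=int)
    in_win = (offsets >= 0) & (offsets < window.length_days)
    if (~in_win).any():
        logger.debug("patient %s: ignoring %d dispensing event(s) outside window",
                     patient_id, int((~in_win).sum()))
    order = np.argsort(offsets[in_win], kind="stable")
    fill_days = offsets[in_win][order]
    fill_supplies = supplies[in_win][order]

    W = window.length_days
    merged = _merged_covered_intervals(fill_days, fill_supplies, W,
                                       config.carryover_policy)
    covered = sum(end - start for start, end in merged)

    run = _max_uncovered_run(merged, fill_days, W, config.gap_scope)
    has_gap = None if run is None else run >= config.gap_threshold_days
    return PatientCoverage(
        patient_id=patient_id,
        covered_days=covered,
        pct_days_covered=100.0 * covered / W,
        max_uncovered_run_days=run,
        has_gap_ge_threshold=has_gap,
        n_fills_in_window=int(len(fill_days)),
    )


def _max_uncovered_run(merged: list[tuple[int, int]], fill_days: np.ndarray,
                       window_days: int, gap_scope: str) -> int | None:
    """Longest run of consecutive uncovered days.

    The search region starts at the first in-window fill day; under
    ``include_trailing`` it extends to the window end, under
    ``between_fills_only`` it stops at the last in-window fill day.
    """
    if len(fill_days) == 0:
        return window_days if gap_scope == "include_trailing" else None
    runs = [merged[i + 1][0] - merged[i][1] for i in range(len(merged) - 1)]
    if gap_scope == "include_trailing":
        runs.append(window_days - merged[-1][1])
    return max(runs, default=0)


def max_uncovered_run(events: pd.DataFrame, window: ObservationWindow,
                      config: SummaryConfig | None = None) -> int | None:
    """Convenience wrapper returning only the longest uncovered run."""
    return coverage(events, window, config).max_uncovered_run_days


def self_report(doses_prescribed_3d: int, doses_missed_3d: int
                ) -> tuple[float, bool] | None:
    """Percentage of doses taken and the perfect-adherence flag.

    Returns ``None`` when no doses were prescribed over the recall period
    (the interview contributes to neither numerator nor denominator).
    """
    if doses_prescribed_3d <= 0:
        return None
    if not 0 <= doses_missed_3d <= doses_prescribed_3d:
        raise ValueError("doses_missed_3d must be in [0, doses_prescribed_3d]")
    pct = 100.0 * (doses_prescribed_3d - doses_missed_3d) / doses_prescribed_3d
    return pct, doses_missed_3d == 0


def punctuality(patient_id: str, scheduled_date, attended_date,
                windows: tuple[int, ...] = (0, 3, 30)) -> PunctualityOutcome:
    """Punctuality flags for one appointment.

    ``days_late = attended - scheduled`` in whole days (negative = early);
    attendance within window k means ``days_late <= k``. A never-attended
    appointment (``attended_date`` None/NaT) fails every window.
    """
    w0, w3, w30 = windows
    if attended_date is None or pd.isna(attended_date):
        return PunctualityOutcome(patient_id, scheduled_date, None,
                                  False, False, False)
    days_late = (attended_date - scheduled_date).days
    return PunctualityOutcome(
        patient_id, scheduled_date, days_late,
        days_late <= w0, days_late <= w3, days_late <= w30,
    )


def patient_coverage_table(dispensing: pd.DataFrame, patients: pd.DataFrame,
                           config: SummaryConfig) -> pd.DataFrame:
    """Per-patient coverage rows for every patient in the roster.

    Each patient's window is anchored at their own ``index_date`` and runs
    ``config.window_days`` days. Dispensing events for patients absent
    from the roster are ignored with a log note. Patients at facilities
    with no dispensing records at all are excluded (the indicator is not
    measurable there, as opposed to measurably zero).
    """
    known = set(patients["patient_id"])
    orphan = ~dispensing["patient_id"].isin(known)
    if orphan.any():
        logger.warning("ignoring %d dispensing event(s) for patients not in roster",
                       int(orphan.sum()))
        dispensing = dispensing[~orphan]

    facilities_with_data = set(dispensing["facility_id"].unique())
    by_patient = dict(list(dispensing.groupby("patient_id", sort=False)))
    empty = dispensing.iloc[0:0]

    rows = []
    for rec in patients.itertuples(index=False):
        if rec.facility_id not in facilities_with_data:
            continue
        window = ObservationWindow(rec.index_date, config.window_days)
        events = by_patient.get(rec.patient_id, empty)
        cov = coverage(events, window, config, patient_id=rec.patient_id)
        rows.append({
            "patient_id": rec.patient_id,
            "facility_id": rec.facility_id,
            "in_treatment_at_end": rec.in_treatment_at_end,
            "covered_days": cov.covered_days,
            "pct_days_covered": cov.pct_days_covered,
            "max_uncovered_run_days": (np.nan if cov.max_uncovered_run_days is None
                                       else cov.max_uncovered_run_days),
            "has_gap_ge_threshold": cov.has_gap_ge_threshold,
            "n_fills_in_window": cov.n_fills_in_window,
        })
    columns = ["patient_id", "facility_id", "in_treatment_at_end", "covered_days",
               "pct_days_covered", "max_uncovered_run_days",
               "has_gap_ge_threshold", "n_fills_in_window"]
    return pd.DataFrame(rows, columns=columns)


def punctuality_table(appointments: pd.DataFrame,
                      config: SummaryConfig) -> pd.DataFrame:
    """Vectorized punctuality flags for every appointment row."""
    sched = pd.to_datetime(appointments["scheduled_date"])
    att = pd.to_datetime(appointments["attended_date"])
    days_late = (att - sched).dt.days
    attended = att.notna()
    w0, w3, w30 = config.punctuality_windows_days
    out = appointments[["patient_id", "facility_id"]].copy()
    out["days_late"] = days_late
    out["attended_on_time"] = attended & (days_late <= w0)
    out["attended_within_3"] = attended & (days_late <= w3)
    out["attended_within_30"] = attended & (days_late <= w30)
    return out


def self_report_table(interviews: pd.DataFrame) -> pd.DataFrame:
    """Per-interview self-report outcomes; zero-dose interviews are dropped."""
    valid = interviews[interviews["doses_prescribed_3d"] > 0]
    taken = valid["doses_prescribed_3d"] - valid["doses_missed_3d"]
    out = valid[["patient_id", "facility_id"]].copy()
    out["pct_doses_taken"] = 100.0 * taken / valid["doses_prescribed_3d"]
    out["perfect"] = valid["doses_missed_3d"] == 0
    return out


def _pct(mask: pd.Series) -> float:
    return float(100.0 * mask.mean()) if len(mask) else np.nan


def facility_indicators(facility_id: str, country: str,
                        coverage_rows: pd.DataFrame,
                        punctuality_rows: pd.DataFrame,
                        self_report_rows: pd.DataFrame,
                        coverage_target_pct: float = 95.0) -> dict:
    """One facility's indicator row from its per-patient tables.

    Every percentage is computed over its own defined denominator; an
    indicator whose data source is absent at this facility (for example no
    dispensing records) is NaN, never zero. Dispensing indicators come in
    an entire-sample variant (including patients lost to follow-up) and an
    in-treatment-at-end variant.
    """
    row: dict = {c: np.nan for c in INDICATOR_COLUMNS}
    row["facility_id"] = facility_id
    row["country"] = country

    row["n_interviews"] = len(self_report_rows)
    if len(self_report_rows):
        row["pct_perfect_self_report"] = _pct(self_report_rows["perfect"])
        row["mean_pct_doses_taken"] = float(self_report_rows["pct_doses_taken"].mean())

    row["n_dispensing_patients"] = len(coverage_rows)
    if len(coverage_rows):
        row["mean_pct_days_covered"] = float(coverage_rows["pct_days_covered"].mean())
        row["pct_patients_coverage_ge_95"] = _pct(
            coverage_rows["pct_days_covered"] >= coverage_target_pct)
        gaps = coverage_rows["has_gap_ge_threshold"].dropna()
        row["pct_patients_gap_ge_30"] = _pct(gaps.astype(bool)) if len(gaps) else np.nan

    in_rx = coverage_rows[coverage_rows["in_treatment_at_end"] == True]  # noqa: E712
    row["n_dispensing_patients_in_treatment"] = len(in_rx)
    if len(in_rx):
        row["mean_pct_days_covered_in_treatment"] = float(
            in_rx["pct_days_covered"].mean())
        row["pct_patients_coverage_ge_95_in_treatment"] = _pct(
            in_rx["pct_days_covered"] >= coverage_target_pct)
        gaps = in_rx["has_gap_ge_threshold"].dropna()
        row["pct_patients_gap_ge_30_in_treatment"] = (
            _pct(gaps.astype(bool)) if len(gaps) else np.nan)

    row["n_appointments"] = len(punctuality_rows)
    if len(punctuality_rows):
        row["pct_attended_on_time"] = _pct(punctuality_rows["attended_on_time"])
        row["pct_attended_within_3"] = _pct(punctuality_rows["attended_within_3"])
        row["pct_attended_within_30"] = _pct(punctuality_rows["attended_within_30"])
    return row


def compute_indicator_table(dispensing: pd.DataFrame, appointments: pd.DataFrame,
                            interviews: pd.DataFrame, patients: pd.DataFrame,
                            facilities: pd.DataFrame,
                            config: SummaryConfig | None = None) -> pd.DataFrame:
    """Facility indicator table across the whole roster.

    The facility roster defines the row set; facilities with no data in a
    source carry missing values for that source's indicators. The
    coverage-target cut uses ``config.coverage_target_pct``.
    """
    config = config or SummaryConfig()
    cov = patient_coverage_table(dispensing, patients, config)
    punct = punctuality_table(appointments, config)
    rep = self_report_table(interviews)

    rows = []
    for fac in facilities.itertuples(index=False):
        row = facility_indicators(
            fac.facility_id, fac.country,
            cov[cov["facility_id"] == fac.facility_id],
            punct[punct["facility_id"] == fac.facility_id],
            rep[rep["facility_id"] == fac.facility_id],
            coverage_target_pct=config.coverage_target_pct,
        )
        rows.append(row)
        n_def = sum(1 for c in INDICATOR_COLUMNS[2:13] if pd.notna(row[c]))
        logger.info("facility %s: %d/11 indicators defined "
                    "(%d interviews, %d dispensing patients, %d appointments)",
                    fac.facility_id, n_def, row["n_interviews"],
                    row["n_dispensing_patients"], row["n_appointments"])
    table = pd.DataFrame(rows, columns=INDICATOR_COLUMNS)
    for c in INDICATOR_COLUMNS[13:]:
        table[c] = table[c].astype(int)
    return table
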