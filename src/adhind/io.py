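"""Readers and writers for the five patient-level CSV tables.

Every table has a bit-exact header contract (see the ``*_COLUMNS``
constants). A missing column is a hard failure naming the column; a
malformed *row* is never fatal — it is excluded and recorded in a
row-indexed reject report so that validation is total: every input row is
either parsed or accounted for.

Dates are ISO 8601 (``YYYY-MM-DD``) in files and ``datetime.date`` objects
in memory; downstream code converts them to integer day offsets relative
to an :class:`~adhind.config.ObservationWindow`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from datetime import date
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DISPENSING_COLUMNS = ["patient_id", "facility_id", "dispense_date", "days_supplied"]
APPOINTMENT_COLUMNS = ["patient_id", "facility_id", "scheduled_date", "attended_date"]
INTERVIEW_COLUMNS = [
    "patient_id", "facility_id", "doses_prescribed_3d", "doses_missed_3d",
    "age_years", "sex", "months_on_treatment", "travel_time_min",
    "wait_time_min", "knows_regimen",
]
PATIENT_COLUMNS = [
    "patient_id", "facility_id", "index_date", "age_years", "sex",
    "months_on_art", "who_stage", "has_pill_count", "has_self_report_note",
    "in_treatment_at_end",
]
FACILITY_COLUMNS = ["facility_id", "country", "facility_type", "patients_per_week"]

SEXES = ("female", "male", "unknown")
WHO_STAGES = ("1", "2", "3", "4", "unknown")

#: Stable column order of the facility indicator table. Percentages are in
#: [0, 100] or empty (indicator undefined at that facility); ``n_*`` columns
#: are the per-indicator denominators.
INDICATOR_COLUMNS = [
    "facility_id", "country",
    "pct_perfect_self_report", "mean_pct_doses_taken",
    "mean_pct_days_covered", "pct_patients_coverage_ge_95",
    "pct_patients_gap_ge_30",
    "mean_pct_days_covered_in_treatment",
    "pct_patients_coverage_ge_95_in_treatment",
    "pct_patients_gap_ge_30_in_treatment",
    "pct_attended_on_time", "pct_attended_within_3", "pct_attended_within_30",
    "n_interviews", "n_dispensing_patients", "n_dispensing_patients_in_treatment",
    "n_appointments",
]


class SchemaError(ValueError):
    """Raised when a file's header does not match the column contract."""


@dataclass
class ReadResult:
    """A parsed table plus its row-indexed reject report.

    ``frame`` holds the rows that passed validation; ``rejects`` has columns
    ``row`` (0-based data-row index in the source file) and ``reason``.
    ``n_input == len(frame) + len(rejects)`` always.
    """

    frame: pd.DataFrame
    rejects: pd.DataFrame
    n_input: int

    @property
    def n_rejected(self) -> int:
        return len(self.rejects)


def _read_raw(path, columns: list[str]) -> pd.DataFrame:
    path = Path(path)
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in columns:
        if col not in raw.columns:
            raise SchemaError(f"{path.name}: missing required column '{col}'")
    return raw[columns]


def _finish(raw: pd.DataFrame, ok: pd.Series, reasons: pd.Series,
            frame: pd.DataFrame, name: str) -> ReadResult:
    rejects = pd.DataFrame({
        "row": np.flatnonzero(~ok.to_numpy()),
        "reason": reasons[~ok].to_numpy(),
    })
    if len(rejects):
        logger.warning("%s: rejected %d of %d rows", name, len(rejects), len(raw))
    return ReadResult(frame[ok].reset_index(drop=True), rejects, len(raw))


def _parse_dates(s: pd.Series) -> pd.Series:
    return pd.to_datetime(s, format="%Y-%m-%d", errors="coerce")


def _parse_num(s: pd.Series) -> pd.Series:
    return pd.to_numeric(s.replace("", np.nan), errors="coerce")


def _accumulate(raw: pd.DataFrame) -> tuple[pd.Series, pd.Series]:
    n = len(raw)
    return (pd.Series(True, index=raw.index),
            pd.Series([""] * n, index=raw.index, dtype=object))


def _flag(ok: pd.Series, reasons: pd.Series, bad: pd.Series, reason: str) -> None:
    new = bad & ok
    ok[new] = False
    reasons[new] = reason


def read_dispensing(path) -> ReadResult:
    """Read pharmacy dispensing events (one row per fill).

    Rejects rows with an unparseable date or a non-positive days-supplied.
    """
    raw = _read_raw(path, DISPENSING_COLUMNS)
    ok, reasons = _accumulate(raw)
    dates = _parse_dates(raw["dispense_date"])
    supply = _parse_num(raw["days_supplied"])
    _flag(ok, reasons, raw["patient_id"].eq(""), "empty patient_id")
    _flag(ok, reasons, raw["facility_id"].eq(""), "empty facility_id")
    _flag(ok, reasons, dates.isna(), "unparseable dispense_date")
    _flag(ok, reasons, supply.isna() | (supply < 1) | (supply != supply.round()),
          "days_supplied must be a positive integer")
    frame = pd.DataFrame({
        "patient_id": raw["patient_id"],
        "facility_id": raw["facility_id"],
        "dispense_date": dates.dt.date,
        "days_supplied": supply.fillna(0).astype(int),
    })
    return _finish(raw, ok, reasons, frame, "dispensing")


def read_appointments(path) -> ReadResult:
    """Read the appointment log. An empty ``attended_date`` means the
    appointment was never attended (all punctuality flags false)."""
    raw = _read_raw(path, APPOINTMENT_COLUMNS)
    ok, reasons = _accumulate(raw)
    sched = _parse_dates(raw["scheduled_date"])
    attended = _parse_dates(raw["attended_date"])
    _flag(ok, reasons, raw["patient_id"].eq(""), "empty patient_id")
    _flag(ok, reasons, sched.isna(), "unparseable scheduled_date")
    _flag(ok, reasons, attended.isna() & raw["attended_date"].ne(""),
          "unparseable attended_date")
    frame = pd.DataFrame({
        "patient_id": raw["patient_id"],
        "facility_id": raw["facility_id"],
        "scheduled_date": sched.dt.date,
        # missing -> never attended; plain NaN so equality with in-memory
        # frames is exact
        "attended_date": attended.dt.date.where(attended.notna(), np.nan),
    })
    return _finish(raw, ok, reasons, frame, "appointments")


def read_interviews(path) -> ReadResult:
    """Read exit interviews (3-day self-reported dose recall plus covariates)."""
    raw = _read_raw(path, INTERVIEW_COLUMNS)
    ok, reasons = _accumulate(raw)
    presc = _parse_num(raw["doses_prescribed_3d"])
    missed = _parse_num(raw["doses_missed_3d"])
    _flag(ok, reasons, raw["patient_id"].eq(""), "empty patient_id")
    _flag(ok, reasons, presc.isna() | (presc < 0), "invalid doses_prescribed_3d")
    _flag(ok, reasons, missed.isna() | (missed < 0) | (missed > presc),
          "doses_missed_3d must be in [0, doses_prescribed_3d]")
    _flag(ok, reasons, ~raw["sex"].isin(SEXES), f"sex must be one of {SEXES}")
    knows = raw["knows_regimen"].str.lower().map(
        {"true": True, "false": False, "": pd.NA})
    frame = pd.DataFrame({
        "patient_id": raw["patient_id"],
        "facility_id": raw["facility_id"],
        "doses_prescribed_3d": presc.fillna(0).astype(int),
        "doses_missed_3d": missed.fillna(0).astype(int),
        "age_years": _parse_num(raw["age_years"]),
        "sex": raw["sex"],
        "months_on_treatment": _parse_num(raw["months_on_treatment"]),
        "travel_time_min": _parse_num(raw["travel_time_min"]),
        "wait_time_min": _parse_num(raw["wait_time_min"]),
        "knows_regimen": knows.astype("boolean"),
    })
    return _finish(raw, ok, reasons, frame, "interviews")


def read_patients(path) -> ReadResult:
    """Read the patient roster (one row per sampled record review)."""
    raw = _read_raw(path, PATIENT_COLUMNS)
    ok, reasons = _accumulate(raw)
    idx = _parse_dates(raw["index_date"])
    _flag(ok, reasons, raw["patient_id"].eq(""), "empty patient_id")
    _flag(ok, reasons, idx.isna(), "unparseable index_date")
    _flag(ok, reasons, ~raw["who_stage"].isin(WHO_STAGES),
          f"who_stage must be one of {WHO_STAGES}")
    _flag(ok, reasons, ~raw["sex"].isin(SEXES), f"sex must be one of {SEXES}")

    def _bool(col: str) -> pd.Series:
        return raw[col].str.lower().map({"true": True, "false": False}).astype("boolean")

    frame = pd.DataFrame({
        "patient_id": raw["patient_id"],
        "facility_id": raw["facility_id"],
        "index_date": idx.dt.date,
        "age_years": _parse_num(raw["age_years"]),
        "sex": raw["sex"],
        "months_on_art": _parse_num(raw["months_on_art"]),
        "who_stage": raw["who_stage"],
        "has_pill_count": _bool("has_pill_count"),
        "has_self_report_note": _bool("has_self_report_note"),
        "in_treatment_at_end": _bool("in_treatment_at_end"),
    })
    return _finish(raw, ok, reasons, frame, "patients")


def read_facilities(path) -> ReadResult:
    """Read the facility roster. Duplicate facility_id is a hard failure."""
    raw = _read_raw(path, FACILITY_COLUMNS)
    dup = raw["facility_id"].duplicated()
    if dup.any():
        raise ValueError(
            f"duplicate facility_id in roster: {sorted(raw['facility_id'][dup].unique())}")
    ok, reasons = _accumulate(raw)
    _flag(ok, reasons, raw["facility_id"].eq(""), "empty facility_id")
    frame = pd.DataFrame({
        "facility_id": raw["facility_id"],
        "country": raw["country"],
        "facility_type": raw["facility_type"],
        "patients_per_week": _parse_num(raw["patients_per_week"]),
    })
    return _finish(raw, ok, reasons, frame, "facilities")


def _date_str(d) -> str:
    return "" if pd.isna(d) else (d.isoformat() if isinstance(d, date) else str(d))


def _write_csv(frame: pd.DataFrame, path, date_cols: list[str] = (),
               bool_cols: list[str] = ()) -> None:
    out = frame.copy()
    for col in date_cols:
        out[col] = out[col].map(_date_str)
    for col in bool_cols:
        out[col] = out[col].map(lambda v: "" if pd.isna(v) else str(bool(v)).lower())
    out.to_csv(path, index=False)


def write_dispensing(frame: pd.DataFrame, path) -> None:
    _write_csv(frame[DISPENSING_COLUMNS], path, date_cols=["dispense_date"])


def write_appointments(frame: pd.DataFrame, path) -> None:
    _write_csv(frame[APPOINTMENT_COLUMNS], path,
               date_cols=["scheduled_date", "attended_date"])


def write_interviews(frame: pd.DataFrame, path) -> None:
    _write_csv(frame[INTERVIEW_COLUMNS], path, bool_cols=["knows_regimen"])


def write_patients(frame: pd.DataFrame, path) -> None:
    _write_csv(frame[PATIENT_COLUMNS], path, date_cols=["index_date"],
               bool_cols=["has_pill_count", "has_self_report_note",
                          "in_treatment_at_end"])


def write_facilities(frame: pd.DataFrame, path) -> None:
    _write_csv(frame[FACILITY_COLUMNS], path)


def write_indicator_table(frame: pd.DataFrame, path) -> None:
    """Write the facility indicator table with stable column order.

    Undefined indicators (facilities where a data source is absent) are
    written as empty cells, never as zero, so that missingness propagates
    to pairwise-deletion correlation downstream.
    """
    if frame["facility_id"].duplicated().any():
        dups = sorted(frame.loc[frame["facility_id"].duplicated(), "facility_id"])
        raise ValueError(f"duplicate facility_id in indicator table: {dups}")
    cols = [c for c in INDICATOR_COLUMNS if c in frame.columns]
    extra = [c for c in frame.columns if c not in cols]
    frame[cols + extra].to_csv(path, index=False)


def read_indicator_table(path) -> pd.DataFrame:
    frame = pd.read_csv(path, dtype={"facility_id": str, "country": str})
    if "facility_id" not in frame.columns:
        raise SchemaError(f"{Path(path).name}: missing required column 'facility_id'")
    return frame
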