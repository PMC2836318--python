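"""Synthetic multi-country ART clinic cohorts.

The generator emulates the data-generating process the indicator set
assumes: patients enter a facility cohort at an index visit (a fill day),
receive a fixed number of days of medicine at each fill, are given a
follow-up appointment a fixed lead time later (28 days for a 30-day
supply, so a patient who returns when medicine runs out is 2 days late
but still covered), and return according to a three-part mixture:

* *on time* — the next fill happens exactly on the scheduled day;
* *short delay* — the next fill is a geometric number of days (mean
  ``short_delay_mean_days``) after the scheduled day;
* *long gap* — the next fill happens ``long_gap_min_days`` or more days
  after the current supply runs out, producing a treatment gap.

Dropout is absorbing: after any fill the patient may stop returning (per
refill-interval hazard derived from ``monthly_dropout_hazard``), leaving
a trailing uncovered run and a missed final appointment. Clinic
attendance is *derived* from the refill process — the attended date of a
scheduled appointment is the next actual fill date — so the correlation
between dispensing and attendance indicators emerges mechanically, the
way it does in clinics where medicine collection and visits co-occur.

Exit interviews over-report adherence deliberately: a patient with
uncovered days reports zero missed doses with probability
``p_report_perfect_given_gap``; otherwise reported missed doses are
proportional to their uncovered fraction of the window. Pill-count and
self-report-note recording flags are drawn at the survey-observed
probabilities (15% and 45%).

Every draw is governed by a single scenario seed via per-facility,
per-patient ``numpy`` seed spawning, so identical configuration yields
byte-identical CSV output, and changing one facility's behavioural
parameter leaves every other patient's draws untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from datetime import date, timedelta
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .config import ObservationWindow
from . import io as aio

COUNTRIES = ("Kenya", "Rwanda", "Uganda", "Ethiopia")
FACILITY_TYPES = ("teaching/referral hospital", "district hospital",
                  "faith-based hospital", "health center/clinic", "other")
DOSES_PER_DAY = 2  # twice-daily regimen: 6 doses over a 3-day recall


@dataclass(frozen=True)
class FacilityProfile:
    """Behavioural and logistical parameters of one synthetic facility."""

    facility_id: str
    country: str
    n_patients: int
    refill_interval_days: int = 30
    appointment_lead_days: int = 28
    p_on_time: float = 0.76
    short_delay_mean_days: float = 5.0
    p_long_gap: float = 0.02
    long_gap_min_days: int = 40
    monthly_dropout_hazard: float = 0.01
    p_report_perfect_given_gap: float = 0.55
    p_pill_count_recorded: float = 0.15
    p_self_report_recorded: float = 0.45
    facility_type: str = "district hospital"
    patients_per_week: float = 176.0
    n_interviews: int | None = None  # default min(30, n_patients)
    has_dispensing_records: bool = True

    def __post_init__(self) -> None:
        probs = {"p_on_time": self.p_on_time, "p_long_gap": self.p_long_gap,
                 "monthly_dropout_hazard": self.monthly_dropout_hazard,
                 "p_report_perfect_given_gap": self.p_report_perfect_given_gap,
                 "p_pill_count_recorded": self.p_pill_count_recorded,
                 "p_self_report_recorded": self.p_self_report_recorded}
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if self.p_on_time + self.p_long_gap > 1.0 + 1e-12:
            raise ValueError("p_on_time + p_long_gap must not exceed 1")
        if self.n_patients < 1:
            raise ValueError("n_patients must be positive")
        if self.refill_interval_days < 1:
            raise ValueError("refill_interval_days must be >= 1")
        if self.appointment_lead_days < 1:
            raise ValueError("appointment_lead_days must be >= 1")
        if self.long_gap_min_days < 1:
            raise ValueError("long_gap_min_days must be >= 1")
        if self.short_delay_mean_days < 1:
            raise ValueError("short_delay_mean_days must be >= 1")


@dataclass(frozen=True)
class ScenarioConfig:
    """A full scenario: facilities, observation window, master seed."""

    facilities: tuple[FacilityProfile, ...]
    window: ObservationWindow
    seed: int
    two_cohort: bool = False
    recent_cohort_days: int = 120

    def __post_init__(self) -> None:
        ids = [f.facility_id for f in self.facilities]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate facility_id in scenario")


def _simulate_fill_history(profile: FacilityProfile, window_days: int,
                           rng: np.random.Generator
                           ) -> tuple[list[int], list[tuple[int, int | None]], bool]:
    """One patient's fill days, (scheduled, attended) appointments, dropout.

    Exactly four random draws are consumed per refill interval regardless
    of the branch taken, so that changing one mixture weight perturbs only
    the affected branch.
    """
    interval = profile.refill_interval_days
    lead = profile.appointment_lead_days
    hazard = 1.0 - (1.0 - profile.monthly_dropout_hazard) ** (interval / 30.0)
    p_short_geom = min(1.0, 1.0 / profile.short_delay_mean_days)

    fills = [0]
    appts: list[tuple[int, int | None]] = []
    dropped = False
    t = 0
    while True:
        sched = t + lead
        u_drop = rng.random()
        u_branch = rng.random()
        s_short = int(rng.geometric(p_short_geom))          # >= 1
        g_extra = int(rng.geometric(0.1)) - 1               # >= 0, mean 9
        if u_drop < hazard:
            dropped = True
            if sched < window_days:
                appts.append((sched, None))
            break
        if u_branch < profile.p_on_time:
            next_t = sched
        elif u_branch < profile.p_on_time + profile.p_long_gap:
            next_t = t + interval + profile.long_gap_min_days + g_extra
        else:
            next_t = sched + s_short
        if sched < window_days:
            appts.append((sched, next_t))
        if next_t >= window_days:
            break
        fills.append(next_t)
        t = next_t
    return fills, appts, dropped


def _uncovered_fraction(fills: list[int], supply: int, window_days: int) -> float:
    """Fraction of window days not covered, stockpile carryover."""
    covered = 0
    bank_end = 0
    for day in fills:
        start = max(day, bank_end)
        bank_end = start + supply
        covered += max(0, min(bank_end, window_days) - start)
    return 1.0 - covered / window_days


def generate_facility(profile: FacilityProfile, window: ObservationWindow,
                      seed: int | np.random.SeedSequence,
                      id_suffix: str = "") -> dict[str, pd.DataFrame]:
    """Generate one facility's patients, dispensing, appointments, interviews.

    Returns a dict of the four patient-level tables (the facility roster
    row is assembled by :func:`generate_scenario`).
    """
    ss = (seed if isinstance(seed, np.random.SeedSequence)
          else np.random.SeedSequence(seed))
    meta_rng = np.random.default_rng(ss)
    patient_seeds = ss.spawn(profile.n_patients)
    W = window.length_days
    start = window.start_date
    supply = profile.refill_interval_days

    n_int = (min(30, profile.n_patients) if profile.n_interviews is None
             else min(profile.n_interviews, profile.n_patients))

    patients, dispensing, appointments = [], [], []
    interview_pool: list[tuple[bool, dict]] = []  # (dropped, candidate row)
    for i, pseed in enumerate(patient_seeds):
        rng = np.random.default_rng(pseed)
        pid = f"{profile.facility_id}-p{i:04d}{id_suffix}"
        fills, appts, dropped = _simulate_fill_history(profile, W, rng)

        for day in fills:
            dispensing.append({
                "patient_id": pid, "facility_id": profile.facility_id,
                "dispense_date": _offset_date(start, day),
                "days_supplied": supply,
            })
        for sched, attended in appts:
            appointments.append({
                "patient_id": pid, "facility_id": profile.facility_id,
                "scheduled_date": _offset_date(start, sched),
                "attended_date": (np.nan if attended is None
                                  else _offset_date(start, attended)),
            })

        age = float(np.clip(rng.normal(36.0, 10.0), 16.0, 80.0))
        sex = "female" if rng.random() < 0.63 else "male"
        months = float(np.exp(rng.normal(np.log(13.0), 0.6)))
        who = str(rng.choice(["1", "2", "3", "4"], p=[0.10, 0.09, 0.45, 0.36]))
        patients.append({
            "patient_id": pid, "facility_id": profile.facility_id,
            "index_date": start, "age_years": round(age, 1), "sex": sex,
            "months_on_art": round(months, 1), "who_stage": who,
            "has_pill_count": bool(rng.random() < profile.p_pill_count_recorded),
            "has_self_report_note": bool(
                rng.random() < profile.p_self_report_recorded),
            "in_treatment_at_end": not dropped,
        })

        u = _uncovered_fraction(fills, supply, W)
        prescribed = DOSES_PER_DAY * 3
        if u <= 0.0:
            missed = 0
        elif rng.random() < profile.p_report_perfect_given_gap:
            missed = 0
        else:
            missed = int(min(prescribed, round(prescribed * u)))
        interview_pool.append((dropped, {
            "patient_id": pid, "facility_id": profile.facility_id,
            "doses_prescribed_3d": prescribed, "doses_missed_3d": missed,
            "age_years": round(age, 1), "sex": sex,
            "months_on_treatment": round(months, 1),
            "travel_time_min": round(float(rng.gamma(2.0, 30.0)), 1),
            "wait_time_min": round(float(rng.gamma(2.0, 60.0)), 1),
            "knows_regimen": (pd.NA if rng.random() < 0.10
                              else bool(rng.random() < 0.9)),
        }))

    # exit interviews only reach patients still attending the clinic:
    # dropped-out patients cannot be sampled at the exit door
    eligible = [idx for idx, (dropped, _) in enumerate(interview_pool)
                if not dropped]
    chosen = sorted(meta_rng.choice(eligible, size=min(n_int, len(eligible)),
                                    replace=False).tolist()) if eligible else []
    interviews = [interview_pool[idx][1] for idx in chosen]

    tables = {
        "patients": pd.DataFrame(patients, columns=aio.PATIENT_COLUMNS),
        "dispensing": pd.DataFrame(dispensing, columns=aio.DISPENSING_COLUMNS),
        "appointments": pd.DataFrame(appointments, columns=aio.APPOINTMENT_COLUMNS),
        "interviews": pd.DataFrame(interviews, columns=aio.INTERVIEW_COLUMNS),
    }
    if not profile.has_dispensing_records:
        # clinics where the register held no usable dispensing data: the
        # fills happened but were never recorded
        tables["dispensing"] = tables["dispensing"].iloc[0:0]
    return tables


def _offset_date(start: date, days: int) -> date:
    return start + timedelta(days=int(days))


def generate_scenario(config: ScenarioConfig,
                      out_dir: str | Path | None = None
                      ) -> dict[str, pd.DataFrame]:
    """Generate every facility and optionally write the five CSVs.

    Deterministic: the same config (including seed) yields identical
    tables and, through the writers, byte-identical files. With
    ``two_cohort=True`` each facility additionally contributes a *recent*
    patient sample observed over ``recent_cohort_days`` whose appointment
    log is kept but whose dispensing is not abstracted (mirroring a
    two-sample record review: a long-term dispensing cohort and a recent
    attendance cohort).
    """
    root = np.random.SeedSequence(config.seed)
    fac_seeds = root.spawn(len(config.facilities))
    parts: dict[str, list[pd.DataFrame]] = {
        "patients": [], "dispensing": [], "appointments": [], "interviews": []}
    roster = []
    for profile, fseed in zip(config.facilities, fac_seeds):
        tables = generate_facility(profile, config.window, fseed)
        for key, frame in tables.items():
            parts[key].append(frame)
        if config.two_cohort:
            recent_window = ObservationWindow(config.window.start_date,
                                              config.recent_cohort_days)
            recent = generate_facility(
                replace(profile, n_interviews=0), recent_window,
                fseed.spawn(1)[0], id_suffix="-r")
            parts["appointments"].append(recent["appointments"])
        roster.append({
            "facility_id": profile.facility_id, "country": profile.country,
            "facility_type": profile.facility_type,
            "patients_per_week": profile.patients_per_week,
        })

    out = {key: pd.concat(frames, ignore_index=True)
           for key, frames in parts.items()}
    out["facilities"] = pd.DataFrame(roster, columns=aio.FACILITY_COLUMNS)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        aio.write_patients(out["patients"], out_dir / "patients.csv")
        aio.write_dispensing(out["dispensing"], out_dir / "dispensing.csv")
        aio.write_appointments(out["appointments"], out_dir / "appointments.csv")
        aio.write_interviews(out["interviews"], out_dir / "interviews.csv")
        aio.write_facilities(out["facilities"], out_dir / "facilities.csv")
    return out


def study_like_scenario(seed: int, n_facilities: int = 79,
                        patients_per_facility: int = 100,
                        window_start: date = date(2006, 10, 1),
                        window_days: int = 180,
                        n_without_dispensing: int = 4,
                        two_cohort: bool = False) -> ScenarioConfig:
    """A heterogeneous multi-country scenario shaped like a four-country
    facility survey.

    Facilities are spread over four East African countries with
    facility-level behavioural parameters drawn around the defaults, plus
    mild country-level shifts, so facility indicator distributions have
    realistic spread. A few facilities keep no dispensing records at all,
    so dispensing indicators are missing there and correlation cells have
    varying n.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 20061001]))
    per = n_facilities // len(COUNTRIES)
    counts = [per + (1 if i < n_facilities % len(COUNTRIES) else 0)
              for i in range(len(COUNTRIES))]
    country_shift = dict(zip(COUNTRIES, (-0.04, 0.06, -0.06, 0.00)))

    profiles = []
    k = 0
    for country, n_fac in zip(COUNTRIES, counts):
        for _ in range(n_fac):
            base_on_time = 0.76 + country_shift[country]
            p_on_time = float(np.clip(rng.normal(base_on_time, 0.10), 0.30, 0.97))
            p_long_gap = float(np.clip(rng.gamma(2.0, 0.012), 0.001, 0.15))
            profiles.append(FacilityProfile(
                facility_id=f"F{k:03d}",
                country=country,
                n_patients=patients_per_facility,
                p_on_time=min(p_on_time, 1.0 - p_long_gap),
                short_delay_mean_days=float(rng.uniform(3.0, 8.0)),
                p_long_gap=p_long_gap,
                monthly_dropout_hazard=float(rng.uniform(0.002, 0.03)),
                p_report_perfect_given_gap=float(rng.uniform(0.30, 0.80)),
                facility_type=str(rng.choice(
                    FACILITY_TYPES, p=[0.32, 0.45, 0.10, 0.09, 0.04])),
                patients_per_week=float(np.round(rng.uniform(30, 800))),
            ))
            k += 1
    without = rng.choice(n_facilities, size=min(n_without_dispensing, n_facilities),
                         replace=False)
    for idx in without:
        profiles[idx] = replace(profiles[idx], has_dispensing_records=False)
    return ScenarioConfig(
        facilities=tuple(profiles),
        window=ObservationWindow(window_start, window_days),
        seed=seed,
        two_cohort=two_cohort,
    )


def load_scenario(path: str | Path) -> ScenarioConfig:
    """Load a scenario from a plain-text (YAML) key-value file.

    Top-level keys: ``seed``, ``window_start`` (ISO date), ``window_days``,
    optional ``two_cohort``/``recent_cohort_days``, and ``facilities`` — a
    list of per-facility blocks whose keys are
    :class:`FacilityProfile` fields.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    window = ObservationWindow(date.fromisoformat(str(raw["window_start"])),
                               int(raw.get("window_days", 180)))
    profiles = tuple(FacilityProfile(**block) for block in raw["facilities"])
    return ScenarioConfig(
        facilities=profiles, window=window, seed=int(raw["seed"]),
        two_cohort=bool(raw.get("two_cohort", False)),
        recent_cohort_days=int(raw.get("recent_cohort_days", 120)),
    )


def save_scenario(config: ScenarioConfig, path: str | Path) -> None:
    """Write a scenario back to the plain-text key-value format."""
    doc = {
        "seed": config.seed,
        "window_start": config.window.start_date.isoformat(),
        "window_days": config.window.length_days,
        "two_cohort": config.two_cohort,
        "recent_cohort_days": config.recent_cohort_days,
        "facilities": [
            {k: v for k, v in vars(p).items()} for p in config.facilities
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
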