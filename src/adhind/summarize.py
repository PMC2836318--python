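"""Pooled percentages, country five-number summaries, and benchmarks.

Two aggregation levels are kept strictly apart and both are emitted:

* *patient-pooled* percentages (every patient or record in the country or
  overall sample counts once) with normal-approximation binomial
  confidence intervals, and
* *facility-level* distributions (each facility's indicator value counts
  once), summarized by median/min/p25/p75/max within country and by
  cross-facility percentile benchmarks overall. Using the facility median
  keeps a handful of outlying facilities from skewing country summaries.

Percentiles use linear interpolation between order statistics
(position ``h = (n - 1) * q``), i.e. numpy's default.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import SummaryConfig

logger = logging.getLogger(__name__)

#: Facility indicator columns where a *lower* value is better (benchmark
#: orientation is reversed: the poor tail is the high percentiles).
LOWER_IS_BETTER = ("pct_patients_gap_ge_30", "pct_patients_gap_ge_30_in_treatment")


@dataclass(frozen=True)
class PooledPercentage:
    """A patient-pooled proportion with its binomial half-width.

    ``ci_halfwidth = z * sqrt(p/100 * (1 - p/100) / n) * 100`` percentage
    points — the plain normal approximation, no continuity correction.
    """

    numerator: int
    n: int
    p: float
    ci_halfwidth: float


@dataclass(frozen=True)
class FiveNumberSummary:
    median: float
    minimum: float
    p25: float
    p75: float
    maximum: float
    n_facilities: int


def pooled_percentage(numerator: int, n: int,
                      config: SummaryConfig | None = None) -> PooledPercentage | None:
    """Pooled percentage with normal-approximation CI half-width.

    Returns ``None`` when ``n`` is zero (undefined proportion).
    """
    config = config or SummaryConfig()
    if n == 0:
        return None
    if not 0 <= numerator <= n:
        raise ValueError(f"numerator {numerator} outside [0, {n}]")
    p = 100.0 * numerator / n
    return PooledPercentage(numerator, n, p, ci_halfwidth(p, n, config.ci_multiplier))


def ci_halfwidth(p: float, n: int, z: float = 1.96) -> float:
    """Half-width (percentage points) of the z * SE binomial interval at
    an observed percentage ``p`` out of ``n`` trials."""
    if n < 1:
        raise ValueError("n must be at least 1")
    frac = p / 100.0
    return z * math.sqrt(frac * (1.0 - frac) / n) * 100.0


def five_number(values) -> FiveNumberSummary | None:
    """Median, min, 25th, 75th percentile, and max of facility values.

    Missing values are dropped first; an empty input yields ``None``.
    """
    arr = np.asarray(pd.Series(values).dropna(), dtype=float)
    if arr.size == 0:
        return None
    mn, p25, med, p75, mx = np.percentile(arr, [0, 25, 50, 75, 100])
    return FiveNumberSummary(float(med), float(mn), float(p25), float(p75),
                             float(mx), int(arr.size))


def country_summary_table(indicator_table: pd.DataFrame,
                          indicator_columns: list[str] | None = None
                          ) -> pd.DataFrame:
    """Five-number facility summaries per country and indicator.

    One row per (country, indicator); facilities where the indicator is
    undefined are excluded from that indicator's summary (their count is
    visible through ``n_facilities``).
    """
    if indicator_columns is None:
        indicator_columns = [c for c in indicator_table.columns
                             if c.startswith(("pct_", "mean_"))]
    rows = []
    for country, group in indicator_table.groupby("country", sort=True):
        for col in indicator_columns:
            s = five_number(group[col])
            if s is None:
                continue
            rows.append({"country": country, "indicator": col,
                         "median": s.median, "minimum": s.minimum,
                         "p25": s.p25, "p75": s.p75, "maximum": s.maximum,
                         "n_facilities": s.n_facilities})
    return pd.DataFrame(rows, columns=["country", "indicator", "median",
                                       "minimum", "p25", "p75", "maximum",
                                       "n_facilities"])


def benchmark(indicator_table: pd.DataFrame,
              config: SummaryConfig | None = None,
              indicator_columns: list[str] | None = None) -> pd.DataFrame:
    """Cross-facility percentile benchmarks, poor tail first.

    For higher-is-better indicators the value printed at the "poor" 5th
    percentile is the 5th percentile of facility values; for
    lower-is-better indicators (the treatment-gap percentage) the
    orientation is reversed and the 95th percentile is printed there, so
    every benchmark row reads poor-to-good left to right. Indicators with
    no defined facility values are excluded with a log note.
    """
    config = config or SummaryConfig()
    if indicator_columns is None:
        indicator_columns = [c for c in indicator_table.columns
                             if c.startswith(("pct_", "mean_"))]
    qs = np.asarray(config.benchmark_percentiles, dtype=float)
    rows = []
    for col in indicator_columns:
        vals = indicator_table[col].dropna().to_numpy(dtype=float)
        if vals.size == 0:
            logger.warning("benchmark: indicator %s has no defined facility "
                           "values; excluded", col)
            continue
        lower_better = col in LOWER_IS_BETTER
        eff = 100.0 - qs if lower_better else qs
        pcts = np.percentile(vals, eff)
        row = {"indicator": col,
               "orientation": "lower_is_better" if lower_better else "higher_is_better",
               "n_facilities": int(vals.size)}
        row.update({f"p{q:g}": float(v) for q, v in zip(qs, pcts)})
        rows.append(row)
    cols = (["indicator", "orientation", "n_facilities"]
            + [f"p{q:g}" for q in qs])
    return pd.DataFrame(rows, columns=cols)


def pooled_table(coverage_rows: pd.DataFrame, punctuality_rows: pd.DataFrame,
                 self_report_rows: pd.DataFrame, facilities: pd.DataFrame,
                 config: SummaryConfig | None = None) -> pd.DataFrame:
    """Patient-pooled indicator estimates by country and overall.

    One row per (country, indicator) plus a TOTAL country, with the
    pooled percentage (or mean), the binomial CI half-width for
    proportions, and the denominator n. The mean-of-percentage rows
    (days covered, doses taken) carry ``z * SE`` of the per-patient
    distribution instead of the binomial half-width.
    """
    config = config or SummaryConfig()
    z = config.ci_multiplier
    country_of = dict(zip(facilities["facility_id"], facilities["country"]))

    def groups(frame):
        by = frame["facility_id"].map(country_of)
        yield "TOTAL", frame
        for country, g in frame.groupby(by, sort=True):
            yield country, g

    rows = []

    def add_proportion(name, frame, mask_col):
        for country, g in groups(frame):
            pooled = pooled_percentage(int(g[mask_col].sum()), len(g), config)
            if pooled is None:
                continue
            rows.append({"country": country, "indicator": name, "value": pooled.p,
                         "ci_halfwidth": pooled.ci_halfwidth, "n": pooled.n})

    def add_mean(name, frame, value_col):
        for country, g in groups(frame):
            if not len(g):
                continue
            vals = g[value_col].to_numpy(dtype=float)
            se = vals.std(ddof=1) / math.sqrt(len(vals)) if len(vals) > 1 else 0.0
            rows.append({"country": country, "indicator": name,
                         "value": float(vals.mean()),
                         "ci_halfwidth": z * se, "n": len(vals)})

    add_proportion("pct_perfect_self_report", self_report_rows, "perfect")
    add_mean("mean_pct_doses_taken", self_report_rows, "pct_doses_taken")
    add_mean("mean_pct_days_covered", coverage_rows, "pct_days_covered")
    cov_target = coverage_rows.assign(
        _ge=coverage_rows["pct_days_covered"] >= config.coverage_target_pct)
    add_proportion("pct_patients_coverage_ge_95", cov_target, "_ge")
    gap_rows = coverage_rows.dropna(subset=["has_gap_ge_threshold"]).assign(
        _gap=lambda f: f["has_gap_ge_threshold"].astype(bool))
    add_proportion("pct_patients_gap_ge_30", gap_rows, "_gap")
    add_proportion("pct_attended_on_time", punctuality_rows, "attended_on_time")
    add_proportion("pct_attended_within_3", punctuality_rows, "attended_within_3")
    add_proportion("pct_attended_within_30", punctuality_rows, "attended_within_30")

    return pd.DataFrame(rows, columns=["country", "indicator", "value",
                                       "ci_halfwidth", "n"])
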