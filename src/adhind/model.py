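"""The modelling surface: :class:`AdherenceStudy` and :class:`AdherenceResults`.

``AdherenceStudy`` is built from the five patient-level tables (or a
directory of CSVs); ``fit()`` runs the whole indicator pipeline and
returns an ``AdherenceResults`` object carrying

* the facility indicator table (one row per facility, the unit of
  aggregation and correlation),
* patient-pooled percentages with binomial confidence half-widths, by
  country and overall,
* country-level five-number facility summaries,
* cross-facility percentile benchmarks with poor/good orientation, and
* the pairwise-deletion Pearson correlation matrix of facility indicators,

plus ``summary()`` — a plain-text report — and writers for the report
bundle.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as aio
from .config import SummaryConfig
from .correlate import correlation_matrix, correlation_square
from .indicators import (compute_indicator_table, patient_coverage_table,
                         punctuality_table, self_report_table)
from .summarize import benchmark, country_summary_table, pooled_table

logger = logging.getLogger(__name__)


class AdherenceStudy:
    """A facility survey dataset ready for indicator computation.

    Parameters
    ----------
    dispensing, appointments, interviews, patients, facilities : DataFrame
        The five validated tables (see :mod:`adhind.io` for the column
        contracts).
    config : SummaryConfig, optional
        Methodology constants; defaults to the standard 180-day window,
        30-day gap threshold, {0, 3, 30} punctuality windows, 95%
        coverage target, z = 1.96, stockpile carryover.
    """

    def __init__(self, dispensing: pd.DataFrame, appointments: pd.DataFrame,
                 interviews: pd.DataFrame, patients: pd.DataFrame,
                 facilities: pd.DataFrame,
                 config: SummaryConfig | None = None) -> None:
        self.dispensing = dispensing
        self.appointments = appointments
        self.interviews = interviews
        self.patients = patients
        self.facilities = facilities
        self.config = config or SummaryConfig()
        if facilities["facility_id"].duplicated().any():
            raise ValueError("duplicate facility_id in facility roster")

    @classmethod
    def from_csv_dir(cls, path: str | Path,
                     config: SummaryConfig | None = None) -> "AdherenceStudy":
        """Build a study from a directory holding the five standard CSVs
        (``dispensing.csv``, ``appointments.csv``, ``interviews.csv``,
        ``patients.csv``, ``facilities.csv``). Malformed rows are dropped
        with a logged count; header violations raise."""
        path = Path(path)
        readers = {
            "dispensing": aio.read_dispensing, "appointments": aio.read_appointments,
            "interviews": aio.read_interviews, "patients": aio.read_patients,
            "facilities": aio.read_facilities,
        }
        frames = {}
        for name, reader in readers.items():
            result = reader(path / f"{name}.csv")
            logger.info("%s: %d rows read, %d rejected", name,
                        result.n_input, result.n_rejected)
            frames[name] = result.frame
        return cls(config=config, **frames)

    @classmethod
    def from_tables(cls, tables: dict[str, pd.DataFrame],
                    config: SummaryConfig | None = None) -> "AdherenceStudy":
        """Build a study from an in-memory table dict (e.g. the output of
        :func:`adhind.simulate.generate_scenario`)."""
        return cls(tables["dispensing"], tables["appointments"],
                   tables["interviews"], tables["patients"],
                   tables["facilities"], config=config)

    def fit(self) -> "AdherenceResults":
        """Run the full pipeline and return the results object."""
        cfg = self.config
        coverage_rows = patient_coverage_table(self.dispensing, self.patients, cfg)
        punctuality_rows = punctuality_table(self.appointments, cfg)
        self_report_rows = self_report_table(self.interviews)
        indicator_table = compute_indicator_table(
            self.dispensing, self.appointments, self.interviews,
            self.patients, self.facilities, cfg)
        pooled = pooled_table(coverage_rows, punctuality_rows,
                              self_report_rows, self.facilities, cfg)
        country_summaries = country_summary_table(indicator_table)
        benchmarks = benchmark(indicator_table, cfg)
        correlations = correlation_matrix(indicator_table)
        return AdherenceResults(
            model=self, config=cfg,
            patient_coverage=coverage_rows,
            punctuality=punctuality_rows,
            self_reports=self_report_rows,
            facility_indicators=indicator_table,
            pooled=pooled,
            country_summaries=country_summaries,
            benchmarks=benchmarks,
            correlations=correlations,
        )


@dataclass
class AdherenceResults:
    """Fitted indicator estimates, their uncertainties, and diagnostics."""

    model: AdherenceStudy
    config: SummaryConfig
    patient_coverage: pd.DataFrame
    punctuality: pd.DataFrame
    self_reports: pd.DataFrame
    facility_indicators: pd.DataFrame
    pooled: pd.DataFrame
    country_summaries: pd.DataFrame
    benchmarks: pd.DataFrame
    correlations: pd.DataFrame

    def correlation_square(self, field: str = "r") -> pd.DataFrame:
        """Square symmetric matrix of ``r`` (or ``p_value``/``n``)."""
        return correlation_square(self.correlations, field=field)

    def pooled_value(self, indicator: str, country: str = "TOTAL"
                     ) -> tuple[float, float, int]:
        """(value, ci_halfwidth, n) for one pooled indicator."""
        sel = self.pooled[(self.pooled["indicator"] == indicator)
                          & (self.pooled["country"] == country)]
        if sel.empty:
            raise KeyError(f"no pooled value for {indicator!r} in {country!r}")
        row = sel.iloc[0]
        return float(row["value"]), float(row["ci_halfwidth"]), int(row["n"])

    def boxplot_data(self) -> pd.DataFrame:
        """Plot-ready box data per country and indicator.

        For each (country, indicator): median, p25, p75, and the
        individual facility values lying outside [p25, p75] — the
        box-and-diamonds convention for facility distributions.
        """
        rows = []
        ind_cols = [c for c in self.facility_indicators.columns
                    if c.startswith(("pct_", "mean_"))]
        for (country, col), g in (
                self.facility_indicators
                .melt(id_vars=["country"], value_vars=ind_cols,
                      var_name="indicator", value_name="value")
                .dropna(subset=["value"])
                .groupby(["country", "indicator"], sort=True)):
            vals = g["value"].to_numpy(dtype=float)
            p25, med, p75 = np.percentile(vals, [25, 50, 75])
            outside = vals[(vals < p25) | (vals > p75)]
            rows.append({
                "country": country, "indicator": col, "median": med,
                "p25": p25, "p75": p75, "n_facilities": len(vals),
                "outside_values": ";".join(f"{v:.1f}" for v in sorted(outside)),
            })
        return pd.DataFrame(rows, columns=["country", "indicator", "median",
                                           "p25", "p75", "n_facilities",
                                           "outside_values"])

    def summary(self) -> str:
        """Plain-text report mirroring the three canonical table layouts:
        pooled patient percentages with CIs, per-country facility
        five-number summaries, and cross-facility benchmarks."""
        fmt = {"float_format": lambda v: f"{v:.1f}"}
        lines = [
            "Adherence and attendance indicator summary",
            "=" * 44,
            f"facilities: {len(self.facility_indicators)}   "
            f"window: {self.config.window_days} d   "
            f"gap threshold: {self.config.gap_threshold_days} d   "
            f"carryover: {self.config.carryover_policy}   "
            f"gap scope: {self.config.gap_scope}",
            "",
            "Patient-pooled indicators (value +/- "
            f"{self.config.ci_multiplier:g}*SE, n)",
            "-" * 44,
        ]
        pooled = self.pooled.copy()
        pooled["value (+/-)"] = [
            f"{v:.1f} ({h:.1f})" for v, h in zip(pooled["value"],
                                                 pooled["ci_halfwidth"])]
        pivot = pooled.pivot_table(index="indicator", columns="country",
                                   values="value (+/-)", aggfunc="first",
                                   sort=False)
        lines.append(pivot.to_string())
        lines += ["", "Facility-level country summaries "
                  "(median; min, p25, p75, max; facilities)", "-" * 44]
        cs = self.country_summaries
        disp = pd.DataFrame({
            "country": cs["country"], "indicator": cs["indicator"],
            "summary": [f"{m:.1f} ({mn:.0f},{q1:.0f},{q3:.0f},{mx:.0f}) n={n}"
                        for m, mn, q1, q3, mx, n in zip(
                            cs["median"], cs["minimum"], cs["p25"],
                            cs["p75"], cs["maximum"], cs["n_facilities"])],
        })
        lines.append(disp.pivot_table(index="indicator", columns="country",
                                      values="summary", aggfunc="first",
                                      sort=False).to_string())
        lines += ["", "Cross-facility benchmarks (poor tail first)", "-" * 44,
                  self.benchmarks.to_string(index=False, **fmt), "",
                  "Facility-indicator correlations (|r| >= 0.3 shown)", "-" * 44]
        strong = self.correlations[
            (self.correlations["indicator_a"] != self.correlations["indicator_b"])
            & (self.correlations["r"].abs() >= 0.3)]
        lines.append(strong.to_string(index=False, **fmt)
                     if len(strong) else "(none)")
        return "\n".join(lines) + "\n"

    def save(self, out_dir: str | Path) -> dict[str, Path]:
        """Write the report bundle and return the paths written."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = {}

        def _write(name, frame):
            p = out_dir / name
            frame.to_csv(p, index=False)
            paths[name] = p

        aio.write_indicator_table(self.facility_indicators,
                                  out_dir / "indicators.csv")
        paths["indicators.csv"] = out_dir / "indicators.csv"
        _write("pooled.csv", self.pooled)
        _write("summary.csv", self.country_summaries)
        _write("benchmark.csv", self.benchmarks)
        _write("correlations.csv", self.correlations)
        _write("boxplot_data.csv", self.boxplot_data())
        report = out_dir / "report.md"
        report.write_text("```\n" + self.summary() + "```\n")
        paths["report.md"] = report
        return paths
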