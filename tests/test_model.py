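"""AdherenceStudy / AdherenceResults surface and the CLI pipeline."""

from datetime import date

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

from adhind.cli import main as cli_main
from adhind.config import ObservationWindow, SummaryConfig
from adhind.model import AdherenceStudy
from adhind.simulate import (FacilityProfile, ScenarioConfig,
                             generate_scenario, study_like_scenario)


@pytest.fixture(scope="module")
def results(small_scenario_tables):
    return AdherenceStudy.from_tables(small_scenario_tables).fit()


class TestResults:
    def test_facility_rows_cover_roster(self, results, small_scenario_tables):
        assert len(results.facility_indicators) == \
            len(small_scenario_tables["facilities"])

    def test_attendance_nesting_in_every_row(self, results):
        t = results.facility_indicators.dropna(
            subset=["pct_attended_on_time", "pct_attended_within_3",
                    "pct_attended_within_30"])
        assert (t["pct_attended_on_time"]
                <= t["pct_attended_within_3"] + 1e-9).all()
        assert (t["pct_attended_within_3"]
                <= t["pct_attended_within_30"] + 1e-9).all()

    def test_facilities_without_dispensing_records(self, results,
                                                   small_scenario_tables):
        """No dispensing data: dispensing indicators missing (not zero),
        attendance still present."""
        with_data = set(small_scenario_tables["dispensing"]["facility_id"])
        t = results.facility_indicators
        absent = t[~t["facility_id"].isin(with_data)]
        assert len(absent) == 2
        assert absent["mean_pct_days_covered"].isna().all()
        assert (absent["n_dispensing_patients"] == 0).all()
        assert absent["pct_attended_within_3"].notna().all()
        # and they are excluded from dispensing summaries
        cs = results.country_summaries
        n_cov = cs[cs["indicator"] == "mean_pct_days_covered"]["n_facilities"].sum()
        n_att = cs[cs["indicator"] == "pct_attended_within_3"]["n_facilities"].sum()
        assert n_cov == n_att - 2

    def test_pooled_halfwidth_consistent_with_binomial_formula(self, results):
        from adhind.summarize import ci_halfwidth
        pooled = results.pooled
        prop = pooled[~pooled["indicator"].str.startswith("mean_")]
        for row in prop.itertuples(index=False):
            assert row.ci_halfwidth == pytest.approx(
                ci_halfwidth(row.value, row.n), abs=1e-9)

    def test_pooled_value_accessor(self, results):
        value, half, n = results.pooled_value("pct_attended_within_3")
        assert 0 <= value <= 100 and half > 0 and n > 0
        with pytest.raises(KeyError):
            results.pooled_value("no_such_indicator")

    def test_summary_renders_one_decimal_tables(self, results):
        text = results.summary()
        assert "Patient-pooled indicators" in text
        assert "pct_attended_within_3" in text
        assert "Cross-facility benchmarks" in text

    def test_boxplot_data_quartiles(self, results):
        box = results.boxplot_data()
        assert set(["country", "indicator", "median", "p25", "p75"]) <= \
            set(box.columns)
        assert (box["p25"] <= box["median"]).all()
        assert (box["median"] <= box["p75"]).all()

    def test_empty_appointments_degrade_gracefully(self, small_scenario_tables):
        tables = dict(small_scenario_tables)
        tables["appointments"] = tables["appointments"].iloc[0:0]
        res = AdherenceStudy.from_tables(tables).fit()
        t = res.facility_indicators
        assert t["pct_attended_on_time"].isna().all()
        assert t["mean_pct_days_covered"].notna().sum() > 0


class TestRoundTripAndCli:
    def test_csv_round_trip_preserves_results(self, tmp_path,
                                              small_scenario_tables, results):
        from adhind.simulate import generate_scenario  # noqa: F401
        from adhind import io as aio
        d = tmp_path / "data"
        d.mkdir()
        aio.write_dispensing(small_scenario_tables["dispensing"],
                             d / "dispensing.csv")
        aio.write_appointments(small_scenario_tables["appointments"],
                               d / "appointments.csv")
        aio.write_interviews(small_scenario_tables["interviews"],
                             d / "interviews.csv")
        aio.write_patients(small_scenario_tables["patients"], d / "patients.csv")
        aio.write_facilities(small_scenario_tables["facilities"],
                             d / "facilities.csv")
        res2 = AdherenceStudy.from_csv_dir(d).fit()
        pd.testing.assert_frame_equal(res2.facility_indicators,
                                      results.facility_indicators)

    def test_cli_full_pipeline_deterministic(self, tmp_path):
        runner = CliRunner()
        args = ["run", "--seed", "5", "--n-facilities", "6",
                "--patients-per-facility", "30"]
        r1 = runner.invoke(cli_main, args + ["--out-dir", str(tmp_path / "x")],
                           catch_exceptions=False)
        r2 = runner.invoke(cli_main, args + ["--out-dir", str(tmp_path / "y")],
                           catch_exceptions=False)
        assert r1.exit_code == 0 and r2.exit_code == 0
        for name in ("indicators.csv", "pooled.csv", "summary.csv",
                     "benchmark.csv", "correlations.csv", "boxplot_data.csv",
                     "report.md"):
            assert (tmp_path / "x" / name).read_bytes() == \
                (tmp_path / "y" / name).read_bytes()

    def test_cli_stagewise_pipeline(self, tmp_path):
        runner = CliRunner()
        data = tmp_path / "data"
        r = runner.invoke(cli_main, [
            "simulate", "--seed", "2", "--n-facilities", "5",
            "--patients-per-facility", "25", "--out-dir", str(data)],
            catch_exceptions=False)
        assert r.exit_code == 0
        ind = tmp_path / "indicators.csv"
        r = runner.invoke(cli_main, [
            "compute",
            "--dispensing", str(data / "dispensing.csv"),
            "--appointments", str(data / "appointments.csv"),
            "--interviews", str(data / "interviews.csv"),
            "--patients", str(data / "patients.csv"),
            "--facilities", str(data / "facilities.csv"),
            "--carryover", "truncate", "--out", str(ind)],
            catch_exceptions=False)
        assert r.exit_code == 0 and ind.exists()
        r = runner.invoke(cli_main, [
            "summarize", "--indicators", str(ind),
            "--out", str(tmp_path / "summary.csv")], catch_exceptions=False)
        assert r.exit_code == 0
        assert (tmp_path / "benchmark.csv").exists()
        r = runner.invoke(cli_main, [
            "correlate", "--indicators", str(ind),
            "--out", str(tmp_path / "correlations.csv")],
            catch_exceptions=False)
        assert r.exit_code == 0
        corr = pd.read_csv(tmp_path / "correlations.csv")
        assert set(["indicator_a", "indicator_b", "r", "p_value", "n"]) == \
            set(corr.columns)

    def test_cli_missing_input_nonzero_exit(self, tmp_path):
        runner = CliRunner()
        r = runner.invoke(cli_main, ["report", "--data-dir",
                                     str(tmp_path / "nope"),
                                     "--out-dir", str(tmp_path / "out")])
        assert r.exit_code != 0
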