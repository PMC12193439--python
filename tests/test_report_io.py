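"""Report assembly, file adapters and the command-line surface."""

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

from clotkit import cli, io, report
from clotkit import synthetic as syn


def make_plate(fold=2.4, n_per_group=5, noise_sd=0.004, lt50_ref=2400.0):
    """Synthetic plate: a control group and a treated group whose LT50 is
    programmed `fold`-times longer."""
    traces, groups = {}, {"control": [], "treated": []}
    for i in range(n_per_group):
        for group, lt50 in (("control", lt50_ref), ("treated", fold * lt50_ref)):
            sid = f"{group}-{i}"
            p = syn.TurbidityParams(
                ct50_true=300.0, lt50_true=lt50, duration=9000.0,
                noise_sd=noise_sd, seed=1000 * i + (0 if group == "control" else 1),
            )
            traces[sid], _ = syn.gen_turbidity_trace(p)
            groups[group].append(sid)
    return traces, groups


class TestRunAssay:
    def test_reference_group_is_unity_at_zero_noise(self):
        traces, groups = make_plate(noise_sd=0.0)
        cfg = report.StudyConfig(groups=groups, reference="control")
        _, summary = report.run_assay(traces, cfg)
        ref = summary.set_index("group").loc["control"]
        assert ref["mean_ru"] == pytest.approx(1.00, abs=1e-9)
        assert ref["sd_ru"] == pytest.approx(0.00, abs=1e-9)

    def test_programmed_fold_change_recovered(self):
        traces, groups = make_plate(fold=2.4)
        cfg = report.StudyConfig(groups=groups, reference="control")
        _, summary = report.run_assay(traces, cfg)
        row = summary.set_index("group").loc["treated"]
        assert abs(row["mean_ru"] - 2.4) <= max(row["sd_ru"], 0.02)

    def test_missing_reference_rejected(self):
        with pytest.raises(ValueError, match="reference"):
            report.StudyConfig(groups={"a": ["s1"]}, reference="b")

    def test_failed_series_logged_not_fatal(self):
        traces, groups = make_plate(n_per_group=3)
        flat = syn.TurbidityParams(baseline=0.05, a_max=0.051, lt50_true=None, duration=3600.0)
        traces["dud"], _ = syn.gen_turbidity_trace(flat)
        groups["treated"].append("dud")
        cfg = report.StudyConfig(groups=groups, reference="control")
        per_series, summary = report.run_assay(traces, cfg)
        dud = per_series.set_index("series_id").loc["dud"]
        assert "no_clotting" in str(dud["flags"])
        assert summary.set_index("group").loc["treated", "n"] == 3

    def test_rerun_is_byte_identical(self, tmp_path):
        traces, groups = make_plate()
        cfg = report.StudyConfig(groups=groups, reference="control", seed=7)
        out = []
        for run in (1, 2):
            per_series, summary = report.run_assay(traces, cfg)
            path = tmp_path / f"summary_{run}.csv"
            summary.to_csv(path, index=False)
            out.append(path.read_bytes())
        assert out[0] == out[1]


class TestFormatTable:
    def test_mean_sd_cell(self):
        df = pd.DataFrame([{"group": "g", "n": 5, "mean_ru": 1.53, "sd_ru": 0.31, "significant": False}])
        assert report.format_table(df)["cell"].iloc[0] == "1.53 (0.31)"

    def test_significance_mark(self):
        df = pd.DataFrame([{"group": "g", "n": 5, "mean_ru": 1.53, "sd_ru": 0.31, "significant": True}])
        assert report.format_table(df)["cell"].iloc[0] == "1.53 * (0.31)"

    def test_median_iqr_cell(self):
        df = pd.DataFrame([{"group": "g", "n": 300, "median": 95.1, "iqr": 44.6, "significant": False}])
        assert report.format_table(df, style="median_iqr")["cell"].iloc[0] == "95.1 [44.6]"

    def test_empty_group_renders_na(self):
        df = pd.DataFrame([{"group": "g", "n": 0, "mean_ru": np.nan, "sd_ru": np.nan, "significant": False}])
        assert report.format_table(df)["cell"].iloc[0] == "n.a."


class TestIO:
    def test_long_csv_round_trip(self, tmp_path):
        traces, _ = make_plate(n_per_group=2)
        path = tmp_path / "plate.csv"
        io.write_traces_long(traces, path)
        back = io.read_traces_long(path)
        assert set(back) == set(traces)
        sid = next(iter(traces))
        assert np.allclose(back[sid].absorbance, traces[sid].absorbance)

    def test_wide_csv_reader(self, tmp_path):
        t = np.arange(0.0, 50.0, 10.0)
        df = pd.DataFrame({"time": t, "A1": t / 50.0, "A2": t / 25.0})
        path = tmp_path / "wide.csv"
        df.to_csv(path, index=False)
        traces = io.read_traces_wide(path)
        assert set(traces) == {"A1", "A2"}
        assert np.allclose(traces["A2"].absorbance, t / 25.0)

    def test_permeation_csv_and_geometry_json(self, tmp_path):
        geom_path = tmp_path / "geom.json"
        geom_path.write_text('{"tubing_inner_diameter": 0.2}')
        csv_path = tmp_path / "perm.csv"
        pd.DataFrame({"time_min": [0, 10, 20], "length_mm": [0.0, 5.0, 10.0]}).to_csv(csv_path, index=False)
        exp = io.read_permeation_csv(csv_path, io.read_geometry(geom_path))
        assert exp.times_s[-1] == 1200.0

    def test_fiber_image_round_trip_with_sidecar(self, tmp_path):
        image, _ = syn.gen_fiber_image(syn.FiberFieldParams(image_size=(64, 64), seed=0))
        path = tmp_path / "field.tif"
        io.write_fiber_image(image, path)
        back = io.read_fiber_image(path)  # nm/px from sidecar
        assert back.nm_per_pixel == image.nm_per_pixel
        assert back.pixels.shape == image.pixels.shape

    def test_clottability_csv_round_trip(self, tmp_path):
        course = syn.gen_clottability_course()
        path = tmp_path / "course.csv"
        io.write_clottability_csv(course, path)
        df = pd.read_csv(path)
        assert {"digestion_min", "clotting_s", "censored", "display_s"} <= set(df.columns)


class TestCLI:
    def test_simulate_and_analyze_turbidity(self, tmp_path):
        runner = CliRunner()
        prefix = tmp_path / "sim"
        r = runner.invoke(cli.main, ["simulate", "--modality", "turbidity", "--seed", "1", "--out", str(prefix)])
        assert r.exit_code == 0, r.output
        out = tmp_path / "metrics.csv"
        r = runner.invoke(cli.main, ["turbidity", str(prefix.with_suffix(".csv")), "--out", str(out)])
        assert r.exit_code == 0, r.output
        df = pd.read_csv(out)
        assert "lt50" in df.columns and df["lt50"].notna().all()

    def test_permeation_subcommand(self, tmp_path):
        import json

        exp = syn.gen_permeation_readings()
        csv_path = tmp_path / "perm.csv"
        pd.DataFrame({"time_min": exp.times_s / 60.0, "length_mm": exp.lengths_mm}).to_csv(csv_path, index=False)
        geom = tmp_path / "geom.json"
        geom.write_text('{"tubing_inner_diameter": 0.2}')
        out = tmp_path / "res.json"
        r = CliRunner().invoke(cli.main, ["permeation", str(csv_path), "--geometry", str(geom), "--out", str(out)])
        assert r.exit_code == 0, r.output
        assert json.loads(out.read_text())["ks_cm2"] == pytest.approx(0.29e-9, rel=1e-6)
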