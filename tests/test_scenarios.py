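"""Scenario construction, ideal-adaptation analytics, config and CSV I/O, CLI."""

import json
import math

import numpy as np
import pandas as pd
import pytest

from arterygr import (
    ModelConfig,
    build_scenario,
    generate_fixture_scenarios,
    ideal_adaptation,
    load_config,
    read_scenario_csv,
    read_timeseries,
    save_config,
    write_scenario_csv,
    write_timeseries,
)
from arterygr.cli import main as cli_main
from arterygr.params import ConfigurationError
from arterygr.scenarios import Scenario, ScenarioError, parse_scenario_name

from conftest import run_quiet


class TestIdealAdaptation:
    @pytest.mark.parametrize("gamma, eps, r_ratio, h_ratio", [
        (1.0, 0.7, 0.8879, 0.8879),   # 30% flow decrease
        (1.0, 1.3, 1.0914, 1.0914),   # 30% flow increase
        (1.5, 1.0, 1.0, 1.5),         # 50% pressure rise: lumen preserved
    ])
    def test_cube_root_law(self, gamma, eps, r_ratio, h_ratio):
        r, h = ideal_adaptation(gamma, eps)
        assert r == pytest.approx(r_ratio, abs=1e-4)
        assert h == pytest.approx(h_ratio, abs=1e-4)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            ideal_adaptation(0.0, 1.0)


class TestScenarioConstruction:
    def test_step_semantics(self):
        s = build_scenario("step_flow", 0.7)
        assert s.eps(-1.0) == 1.0
        assert s.eps(1e-6) == pytest.approx(0.7)
        assert s.eps(250.0) == pytest.approx(0.7)
        assert s.gamma(100.0) == 1.0

    def test_ramp_interpolates_linearly(self):
        s = build_scenario("ramp_pressure", 1.5, ramp_days=10.0)
        assert s.gamma(5.0) == pytest.approx(1.25)
        assert s.gamma(10.0) == pytest.approx(1.5)
        assert s.gamma(50.0) == pytest.approx(1.5)  # constant extrapolation

    def test_name_parsing(self):
        assert parse_scenario_name("step_flow_0.7").eps(1.0) == pytest.approx(0.7)
        assert parse_scenario_name("step_pressure_1.5").gamma(1.0) == pytest.approx(1.5)
        with pytest.raises(ScenarioError):
            parse_scenario_name("nonsense_scenario")

    def test_rejects_nonpositive_course(self):
        with pytest.raises(ScenarioError):
            Scenario("bad", [0.0], [1.0], [0.0, 1.0], [1.0, -0.5])

    def test_csv_round_trip(self, tmp_path):
        s = Scenario("rt", [0.0, 10.0, 30.0], [1.0, 1.4, 1.2], [0.0, 20.0], [1.0, 0.6])
        p = tmp_path / "scn.csv"
        write_scenario_csv(s, p)
        back = read_scenario_csv(p)
        for t in np.linspace(0, 40, 23):
            assert back.gamma(t) == pytest.approx(s.gamma(t), rel=1e-12)
            assert back.eps(t) == pytest.approx(s.eps(t), rel=1e-12)

    def test_malformed_csv_reports_line(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("t_day,gamma,eps\n0,1.0,1.0\n5,,0.7\n")
        with pytest.raises(ScenarioError, match="line 3"):
            read_scenario_csv(p)


class TestFixtureScenarios:
    def test_deterministic_by_seed(self, tmp_path):
        a = generate_fixture_scenarios(11, tmp_path / "a")
        b = generate_fixture_scenarios(11, tmp_path / "b")
        assert [p.name for p in a] == [p.name for p in b]
        for pa, pb in zip(a, b):
            assert pa.read_bytes() == pb.read_bytes()

    def test_bounds_and_canonical_steps(self, tmp_path):
        paths = generate_fixture_scenarios(3, tmp_path)
        names = {p.stem for p in paths}
        assert {"step_flow_0.7", "step_flow_1.3", "step_pressure_1.5"} <= names
        for p in paths:
            s = read_scenario_csv(p)
            t = np.linspace(0, 60, 200)
            assert np.all(s.gamma(t) >= 1.0 - 1e-9) and np.all(s.gamma(t) <= 1.65 + 1e-9)
            assert np.all(s.eps(t) >= 0.3 - 1e-9) and np.all(s.eps(t) <= 1.3 + 1e-9)


class TestConfigIO:
    def test_round_trip_idempotent(self, tmp_path):
        cfg = ModelConfig().replace(K_sigma_c=6.0, **{"kinetics.beta2": 0.05})
        p = tmp_path / "cfg.yaml"
        save_config(cfg, p)
        back = load_config(p)
        assert back.to_dict() == cfg.to_dict()
        save_config(back, tmp_path / "cfg2.yaml")
        assert (tmp_path / "cfg.yaml").read_text() == (tmp_path / "cfg2.yaml").read_text()

    def test_partial_config(self, tmp_path):
        p = tmp_path / "partial.yaml"
        p.write_text("gains:\n  K_sigma_c: 6.0\n")
        cfg = load_config(p)
        assert cfg.gains.K_sigma_c == 6.0
        assert cfg.wall.r_oh == 0.328  # untouched defaults

    def test_unknown_key_rejected(self, tmp_path):
        p = tmp_path / "bad.yaml"
        p.write_text("gains:\n  K_bogus: 1.0\n")
        with pytest.raises(ConfigurationError):
            load_config(p)

    def test_invariant_validation(self):
        with pytest.raises(ConfigurationError):
            ModelConfig().replace(**{"wall.phi0_e": 0.5})  # fractions no longer sum to 1


class TestTimeseriesIO:
    def test_round_trip_exact_and_shape(self, tmp_path, config):
        res = run_quiet(build_scenario("step_flow", 1.0), config, duration=5.0)
        p = tmp_path / "ts.csv"
        write_timeseries(res, p)
        back = read_timeseries(p)
        assert len(back) == 6  # duration/output_interval + 1 rows
        for col in res.frame.columns:
            assert np.array_equal(back[col].to_numpy(), res.frame[col].to_numpy())

    def test_homeostatic_ratio_columns_are_unity(self, tmp_path, homeostatic_run):
        p = tmp_path / "h.csv"
        write_timeseries(homeostatic_run, p)
        back = read_timeseries(p)
        assert np.allclose(back["M_Rc_ratio"], 1.0, atol=1e-6)
        assert np.allclose(back["M_Rm_ratio"], 1.0, atol=1e-6)
        assert np.allclose(back["tau_ratio"], 1.0, atol=1e-6)

    def test_refuses_empty(self):
        with pytest.raises(ValueError):
            write_timeseries(pd.DataFrame(columns=["t_day"]), "/tmp/never.csv")


class TestCli:
    def test_missing_scenario_is_usage_error(self, capsys):
        with pytest.raises(SystemExit) as exc:
            cli_main([])
        assert exc.value.code == 2

    def test_unknown_scenario_exits_2(self, tmp_path):
        rc = cli_main(["--scenario", "bogus_name", "--out", str(tmp_path / "o.csv")])
        assert rc == 2

    def test_short_run_writes_csv_and_manifest(self, tmp_path):
        out = tmp_path / "run.csv"
        rc = cli_main(["--scenario", "step_flow_0.7", "--duration", "3",
                       "--out", str(out)])
        assert rc == 0
        assert out.exists()
        manifest = json.loads(out.with_suffix(".manifest.json").read_text())
        assert manifest["dt"] == pytest.approx(0.1)
        assert manifest["scenario"]["name"] == "step_flow_0.7"
        assert "config" in manifest and "hash" in manifest["scenario"]

    def test_sweep_produces_one_file_per_value(self, tmp_path):
        out = tmp_path / "sweep.csv"
        rc = cli_main(["--scenario", "step_flow_0.7", "--duration", "2",
                       "--sweep", "Ksigma=0,2", "--out", str(out)])
        assert rc == 0
        assert (tmp_path / "sweep_Ksigma0.csv").exists()
        assert (tmp_path / "sweep_Ksigma2.csv").exists()

    def test_fixtures_mode(self, tmp_path):
        rc = cli_main(["--fixtures", "5", "--out", str(tmp_path / "fix")])
        assert rc == 0
        assert (tmp_path / "fix" / "step_pressure_1.5.csv").exists()
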