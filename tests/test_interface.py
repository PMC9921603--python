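"""I/O, configuration and CLI tests."""

import json

import numpy as np
import pytest
import yaml
from click.testing import CliRunner

from elbowstiff.cli import main as cli_main
from elbowstiff.config import PipelineConfig
from elbowstiff.errors import SchemaError
from elbowstiff.io import (read_params_json, read_trial_csv, write_params_json,
                           write_trial_csv)
from elbowstiff.parameters import PARAM_NAMES, default_ground_truth_vector


class TestTrialIO:
    def test_roundtrip_lossless(self, tmp_path):
        rng = np.random.default_rng(0)
        t = np.arange(0, 1, 0.01)
        ag, ant = rng.random(len(t)), rng.random(len(t))
        angle = rng.uniform(0, 150, len(t))
        path = tmp_path / "trial.csv"
        write_trial_csv(path, t, ag, ant, angle)
        rec = read_trial_csv(path)
        assert np.array_equal(rec.time, t)
        assert np.array_equal(rec.trial.emg_agonist, ag)
        assert np.array_equal(rec.angle_deg, angle)
        assert np.allclose(rec.angle, np.radians(angle))

    def test_missing_column(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("time,emg_ag,emg_ant\n0,0,0\n0.01,0,0\n")
        with pytest.raises(SchemaError, match="angle_deg"):
            read_trial_csv(path)

    def test_hand_written_fixture(self, tmp_path):
        path = tmp_path / "three.csv"
        path.write_text("time,emg_ag,emg_ant,angle_deg\n"
                        "0.00,0.10,0.05,0.0\n0.01,0.20,0.04,45.0\n0.02,0.15,0.06,90.0\n")
        rec = read_trial_csv(path)
        assert rec.trial.fs == pytest.approx(100.0)
        assert rec.angle[2] == pytest.approx(np.pi / 2)

    def test_nan_reported_with_row(self, tmp_path):
        path = tmp_path / "nan.csv"
        path.write_text("time,emg_ag,emg_ant,angle_deg\n0,0,0,0\n0.01,,0,10\n0.02,0,0,20\n")
        with pytest.raises(SchemaError, match="row 1"):
            read_trial_csv(path)

    def test_non_monotone_time(self, tmp_path):
        path = tmp_path / "mono.csv"
        path.write_text("time,emg_ag,emg_ant,angle_deg\n0,0,0,0\n0.02,0,0,1\n0.01,0,0,2\n")
        with pytest.raises(SchemaError, match="row 2"):
            read_trial_csv(path)


class TestParamsIO:
    def test_roundtrip(self, tmp_path):
        vec = default_ground_truth_vector()
        path = tmp_path / "params.json"
        write_params_json(path, vec)
        assert np.allclose(read_params_json(path), vec)
        stored = json.loads(path.read_text())["parameters"]
        assert set(stored) == set(PARAM_NAMES)

    def test_missing_parameter(self, tmp_path):
        path = tmp_path / "partial.json"
        path.write_text(json.dumps({"parameters": {"F_max": 2000.0}}))
        with pytest.raises(SchemaError):
            read_params_json(path)


class TestConfig:
    def test_defaults_are_published_constants(self):
        cfg = PipelineConfig()
        assert cfg.emg.bandpass == [10.0, 500.0]
        assert cfg.emg.notch == [48.0, 52.0]
        assert cfg.activation.A == -20.0
        assert cfg.ga.population_size == 20
        assert cfg.ga.crossover_fraction == 0.7
        assert cfg.ga.elite_count == 2
        assert cfg.ga.stall_tol == 1e-6
        assert cfg.ga.stall_generations == 20
        assert cfg.rls.p0 == 0.01

    def test_yaml_roundtrip_identity(self, tmp_path):
        cfg = PipelineConfig()
        cfg.ga.seed = 17
        path = tmp_path / "cfg.yaml"
        cfg.dump(path)
        again = PipelineConfig.load(path)
        assert again.to_dict() == cfg.to_dict()

    def test_unknown_keys_rejected(self, tmp_path):
        path = tmp_path / "bad.yaml"
        path.write_text(yaml.safe_dump({"ga": {"popsize": 10}}))
        with pytest.raises(SchemaError, match="popsize"):
            PipelineConfig.load(path)
        path.write_text(yaml.safe_dump({"optimizer": {}}))
        with pytest.raises(SchemaError, match="optimizer"):
            PipelineConfig.load(path)


class TestCLI:
    @pytest.fixture()
    def runner(self):
        return CliRunner()

    def test_synth_and_process(self, runner, tmp_path):
        out = tmp_path / "data"
        r = runner.invoke(cli_main, ["synth", "--scenario", "single", "--tempo", "30",
                                     "--reps", "2", "--seed", "3", "--out", str(out)])
        assert r.exit_code == 0, r.output
        trial = next(out.glob("*.csv"))
        act = tmp_path / "act.csv"
        r = runner.invoke(cli_main, ["process-emg", "--data", str(trial),
                                     "--out", str(act)])
        assert r.exit_code == 0, r.output
        arr = np.loadtxt(act, delimiter=",", skiprows=1)
        assert arr.shape[1] == 5
        assert np.all((arr[:, 2] >= 0) & (arr[:, 2] <= 1))

    def test_identify_simulate_validate_chain(self, runner, tmp_path):
        data = tmp_path / "data"
        runner.invoke(cli_main, ["synth", "--scenario", "single", "--reps", "2",
                                 "--seed", "3", "--out", str(data)])
        trial = next(data.glob("*.csv"))
        cfg_path = tmp_path / "cfg.yaml"
        cfg = PipelineConfig()
        cfg.ga.max_generations = 2
        cfg.dump(cfg_path)
        params = tmp_path / "params.json"
        r = runner.invoke(cli_main, ["identify", "--data", str(trial), "--config",
                                     str(cfg_path), "--seed", "5", "--out", str(params)])
        assert r.exit_code == 0, r.output
        sim_csv = tmp_path / "sim.csv"
        r = runner.invoke(cli_main, ["simulate", "--data", str(trial), "--params",
                                     str(params), "--out", str(sim_csv)])
        assert r.exit_code == 0, r.output
        stiff_csv = tmp_path / "stiff.csv"
        r = runner.invoke(cli_main, ["stiffness", "--sim", str(sim_csv),
                                     "--out", str(stiff_csv)])
        assert r.exit_code == 0, r.output
        report = tmp_path / "report.json"
        r = runner.invoke(cli_main, ["validate", "--measured", str(trial), "--params",
                                     str(params), "--report", str(report)])
        assert r.exit_code == 0, r.output
        rep = json.loads(report.read_text())
        assert rep["percent_of_range"] >= 0

    def test_scales_command(self, runner, tmp_path):
        areas = tmp_path / "areas.csv"
        tempos = np.array([15.0, 30.0, 45.0, 60.0])
        np.savetxt(areas, np.column_stack([tempos, 0.001975 * tempos**1.709]),
                   delimiter=",", header="tempo,value", comments="")
        out = tmp_path / "scale.json"
        r = runner.invoke(cli_main, ["scales", "--areas", str(areas), "--model",
                                     "power", "--out", str(out)])
        assert r.exit_code == 0, r.output
        fit = json.loads(out.read_text())
        assert fit["b"] == pytest.approx(1.709, rel=1e-6)

    def test_error_exits_nonzero_with_record(self, runner, tmp_path):
        bad = tmp_path / "bad.csv"
        bad.write_text("time,emg_ag\n0,0\n")
        r = runner.invoke(cli_main, ["process-emg", "--data", str(bad),
                                     "--out", str(tmp_path / "x.csv")])
        assert r.exit_code == 1
        assert "SchemaError" in r.output or "SchemaError" in (r.stderr or "")
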