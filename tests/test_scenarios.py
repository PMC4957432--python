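"""Presets, validation, YAML/manifest round-trips, CLI surface."""

import dataclasses
import json
import math

import pytest
from click.testing import CliRunner

from nefire import (
    Channel,
    ConfigurationError,
    EnvelopeParams,
    FiringThreshold,
    InvalidInputError,
    MODEL_PARAMS,
    Pore,
    ReleaseAmount,
    Scenario,
    SimulationConfig,
    SphereGeometry,
    SphericalPoint,
    Surface,
    build_manifest,
    default_config,
    load_scenario,
    preset,
    run,
    run_from_manifest,
    save_scenario,
    validate,
    write_outputs,
)
from nefire.cli import main as cli_main
from nefire.scenarios import config_from_dict, scenario_from_dict


class TestPresets:
    def test_fig4_counts_and_constants(self):
        s = preset("fig4", seed=0)
        assert len([c for c in s.channels if c.side == "outer"]) == 24
        assert len([c for c in s.channels if c.side == "inner"]) == 24
        assert len(s.pores) == 1500
        assert s.outer.D == 20.0 and s.inner.D == 5.0
        assert s.outer.k_s == 1.0
        assert s.geometry.radius == 8.0
        assert s.pores[0].diameter == 0.029
        assert s.channels[0].release.sigma_mol == 2.0e-20
        assert s.channels[0].threshold.c_th == 0.0425
        assert s.channels[0].threshold.alpha == 0.15

    def test_fig4_pore_density_matches_canonical_count(self):
        s = preset("fig4")
        density = len(s.pores) / s.geometry.area
        assert round(density, 1) == 1.9

    def test_fig2_single_channel_with_inner_probe(self):
        s = preset("fig2")
        assert len(s.channels) == 1 and s.channels[0].side == "outer"
        assert [p.name for p in s.probes] == ["P_N"]
        assert s.probes[0].side == "inner"
        assert s.outer.D == s.inner.D

    def test_fig3_arc_queue_between_channel_and_probe(self):
        s = preset("fig3")
        assert s.outer.D == 2.0 and s.inner.D == 15.0
        from nefire import great_circle_distance

        d = [great_circle_distance(s.channels[0].position, p.position, s.geometry)
             for p in s.pores]
        assert d == sorted(d)  # queued outward from C
        assert max(d) < great_circle_distance(
            s.channels[0].position, s.probes[0].position, s.geometry
        )

    def test_seeded_presets_are_deterministic(self):
        a, b = preset("fig4", seed=5), preset("fig4", seed=5)
        assert a.channels[3].position == b.channels[3].position
        c = preset("fig4", seed=6)
        assert a.channels[3].position != c.channels[3].position

    def test_unknown_preset_rejected(self):
        with pytest.raises(InvalidInputError):
            preset("fig5")


class TestValidate:
    def test_clean_preset_has_no_errors(self):
        findings = validate(preset("fig4", seed=0), default_config("fig4"))
        assert not [f for f in findings if f.level == "error"]

    def test_missing_stimulus_channel_flagged(self):
        cfg = dataclasses.replace(
            default_config("fig4"), initial_stimulus=("inner", 99, 0.0)
        )
        findings = validate(preset("fig4"), cfg)
        assert any(f.code == "bad-stimulus" and f.level == "error" for f in findings)

    def test_pore_on_channel_flagged(self):
        geom = SphereGeometry(8.0)
        pos = SphericalPoint(math.pi / 2, 1.0)
        scen = Scenario(
            geometry=geom,
            outer=Surface("outer", 20.0, 1.0),
            inner=Surface("inner", 5.0, 1.0),
            channels=[Channel(pos, "outer", ReleaseAmount(2e-20),
                              FiringThreshold(0.0425, 0.15), tau_R=1.0)],
            pores=[Pore(pos, 0.029)],
            envelope=EnvelopeParams(0.01, 20.0),
        )
        findings = validate(scen, SimulationConfig(initial_stimulus=("outer", 0, 0.0)))
        assert any(f.code == "pore-collision" for f in findings)


class TestRoundTrips:
    def test_yaml_round_trip_preserves_everything(self, tmp_path):
        scen = preset("fig3")
        cfg = default_config("fig3")
        path = tmp_path / "scenario.yaml"
        save_scenario(scen, path, cfg)
        scen2, cfg2 = load_scenario(path)
        assert scen2 == scen
        assert cfg2 == cfg

    def test_unknown_keys_rejected(self):
        with pytest.raises(ConfigurationError):
            scenario_from_dict({"geometry": {"radius": 8.0}, "wings": 2})
        with pytest.raises(ConfigurationError):
            config_from_dict({"dt": 0.1, "warp_factor": 9})

    def test_manifest_reruns_bitwise_identically(self, tmp_path):
        scen = preset("fig2", n_pores=48)
        cfg = dataclasses.replace(default_config("fig2"), t_end=1.5,
                                  stop_probe=None)
        rec = run(cfg, scen)
        write_outputs(rec, tmp_path, scen, cfg)
        rec2 = run_from_manifest(tmp_path / "manifest.json")
        assert rec.events.equals(rec2.events)
        assert rec.probe_traces.equals(rec2.probe_traces)
        assert rec.pulse_sums.equals(rec2.pulse_sums)

    def test_manifest_records_normalisation_and_version(self):
        m = build_manifest(preset("fig2", n_pores=8), default_config("fig2"))
        assert "uM*" in m["normalisation"]
        assert m["nefire_version"]
        assert m["config"]["dt"] == 0.05

    def test_write_outputs_produces_expected_files(self, tmp_path):
        scen = preset("fig2", n_pores=8)
        cfg = dataclasses.replace(default_config("fig2"), t_end=0.5,
                                  stop_probe=None)
        written = write_outputs(run(cfg, scen), tmp_path, scen, cfg)
        names = {p.name for p in written}
        assert {"events.csv", "traces.csv", "probe_traces.csv",
                "pulse_sums.csv", "manifest.json"} <= names


class TestCli:
    def test_validate_command_ok(self, tmp_path):
        path = tmp_path / "s.yaml"
        save_scenario(preset("fig4"), path, default_config("fig4"))
        result = CliRunner().invoke(cli_main, ["validate", "--config", str(path)])
        assert result.exit_code == 0, result.output
        assert "ok" in result.output

    def test_validate_command_flags_bad_stimulus(self, tmp_path):
        path = tmp_path / "s.yaml"
        cfg = dataclasses.replace(
            default_config("fig4"), initial_stimulus=("inner", 99, 0.0)
        )
        save_scenario(preset("fig4"), path, cfg)
        result = CliRunner().invoke(cli_main, ["validate", "--config", str(path)])
        assert result.exit_code == 1
        assert "bad-stimulus" in result.output

    def test_simulate_command_writes_outputs(self, tmp_path):
        path = tmp_path / "s.yaml"
        cfg = dataclasses.replace(default_config("fig2"), t_end=0.5,
                                  stop_probe=None)
        save_scenario(preset("fig2", n_pores=8), path, cfg)
        out = tmp_path / "out"
        result = CliRunner().invoke(
            cli_main, ["simulate", "--config", str(path), "--out", str(out)]
        )
        assert result.exit_code == 0, result.output
        assert (out / "manifest.json").exists()
        manifest = json.loads((out / "manifest.json").read_text())
        assert manifest["config"]["t_end"] == 0.5
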