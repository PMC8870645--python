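import json

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

import ringsim as rs
from ringsim.cli import main as cli_main
from ringsim.protocol import (ExperimentConfig, ProtocolEvent,
                              events_from_jsonl, events_to_jsonl, load_config)


class TestConfig:
    def test_defaults_valid_and_model_specific(self):
        assert rs.default_config("A").naming_reps == 1
        assert rs.default_config("B").naming_reps == 5

    @pytest.mark.parametrize("bad", [
        {"reward_delays_s": (2,)},
        {"inter_trial_gap_s": 30},
        {"precond_reps": 5},
        {"conditioning_reps": 10},
        {"K": 3},
    ])
    def test_invariants_enforced(self, bad):
        with pytest.raises(ValueError):
            ExperimentConfig(**bad)

    def test_yaml_round_trip_and_unknown_keys(self, tmp_path):
        path = tmp_path / "cfg.yaml"
        path.write_text("seed: 7\nsigma_noise: 0.0\nconditioning_reps: 4\n")
        cfg = load_config(path)
        assert (cfg.seed, cfg.sigma_noise, cfg.conditioning_reps) == (7, 0.0, 4)
        path.write_text("seeed: 7\n")
        with pytest.raises(ValueError, match="unknown config keys"):
            load_config(path)


class TestBuildProtocol:
    def test_four_stimuli_named_in_stage_one(self):
        events = rs.build_protocol(rs.default_config("B"))
        labeled = {e.stimulus for e in events if e.kind == "label"}
        assert labeled == {0, 1, 2, 3}

    def test_pair_trial_count(self):
        cfg = rs.default_config("B", precond_reps=6)
        events = rs.build_protocol(cfg)
        naming_end = max(e.t_end for e in events if e.kind == "label")
        # first conditioning trial begins 1 step before its first reward
        cond_start = min(e.t_start for e in events if e.kind == "reward") - 1
        pair_shows = [e for e in events if e.kind == "show"
                      and naming_end < e.t_start < cond_start]
        assert len(pair_shows) == 24  # 12 pair trials x 2 members

    def test_gaps_exceed_thirty_seconds(self):
        cfg = rs.default_config("B")
        events = sorted((e for e in rs.build_protocol(cfg)
                         if e.kind == "show"), key=lambda e: e.t_start)
        naming_end = max(e.t_end for e in rs.build_protocol(cfg)
                         if e.kind == "label")
        gap_steps = 30 / cfg.dt
        prev_end = None
        for e in events:
            if prev_end is not None and e.t_start > prev_end:
                # separations between trials (paired members are gapless)
                if e.t_start - prev_end > 1:
                    assert e.t_start - prev_end > gap_steps
            prev_end = max(prev_end or 0, e.t_end)

    def test_pure_function_of_config(self):
        cfg = rs.default_config("B")
        assert rs.build_protocol(cfg) == rs.build_protocol(cfg)

    def test_event_validation(self):
        with pytest.raises(ValueError):
            ProtocolEvent(5, 4, "show", 0)
        with pytest.raises(ValueError):
            ProtocolEvent(0, 1, "flash", 0)

    def test_jsonl_round_trip(self):
        events = rs.build_protocol(rs.default_config("A"))
        assert events_from_jsonl(events_to_jsonl(events)) == events


class TestRunProtocol:
    def test_empty_event_list_gives_empty_traces(self):
        cfg = rs.default_config("B")
        traces = rs.run_protocol(rs.build_model("B", cfg), [], cfg)
        assert len(traces) == 0

    def test_traces_are_complete_and_deterministic(self):
        cfg = rs.default_config("B", precond_reps=6, conditioning_reps=3,
                                probe_reps=1, naming_reps=1)
        events = rs.build_protocol(cfg)
        runs = []
        for _ in range(2):
            model = rs.build_model("B", cfg)
            runs.append(rs.run_protocol(model, events, cfg))
        pd.testing.assert_frame_equal(runs[0], runs[1])
        piv = runs[0].pivot(index="t", columns="signal", values="value")
        horizon = max(e.t_end for e in events) + 15
        assert len(piv) == horizon          # every step recorded
        assert not piv.isna().any().any()   # every signal at every step

    def test_unsorted_events_rejected(self):
        cfg = rs.default_config("B")
        events = [ProtocolEvent(50, 60, "show", 0),
                  ProtocolEvent(0, 10, "show", 1)]
        with pytest.raises(ValueError):
            rs.run_protocol(rs.build_model("B", cfg), events, cfg)


class TestProbeSummary:
    def test_all_zero_traces_give_zero_contrasts(self):
        events = [ProtocolEvent(0, 5, "probe_marker", s) for s in range(4)]
        traces = pd.DataFrame(
            {"t": range(5), "signal": ["z"] * 5, "value": [0.0] * 5})
        summary = rs.probe_summary(traces, events)
        assert summary["contrast_AC"] == 0.0
        assert summary["contrast_BD"] == 0.0

    def test_missing_probe_windows_rejected(self):
        traces = pd.DataFrame({"t": [0], "signal": ["z"], "value": [0.0]})
        with pytest.raises(ValueError):
            rs.probe_summary(traces, [])


class TestCli:
    def test_demo_proposition1(self):
        result = CliRunner().invoke(cli_main, ["demo-proposition1",
                                               "--h", "1,0",
                                               "--presentations", "5"])
        assert result.exit_code == 0
        assert "r_B one step after presenting A alone: 1.0000" in result.output

    def test_run_and_probe_round_trip(self, tmp_path):
        out = tmp_path / "traces.csv"
        ev = tmp_path / "events.jsonl"
        summ = tmp_path / "summary.json"
        cfg = tmp_path / "cfg.yaml"
        cfg.write_text("precond_reps: 6\nconditioning_reps: 3\n"
                       "probe_reps: 1\nnaming_reps: 1\nsigma_noise: 0.0\n")
        runner = CliRunner()
        result = runner.invoke(cli_main, [
            "run", "--model", "B", "--config", str(cfg), "--seed", "3",
            "--out", str(out), "--events", str(ev), "--summary", str(summ)])
        assert result.exit_code == 0, result.output
        summary = json.loads(summ.read_text())
        assert summary["contrast_BD"] > 0
        probe = runner.invoke(cli_main, ["probe", "--traces", str(out),
                                         "--events", str(ev)])
        assert probe.exit_code == 0
        assert json.loads(probe.output)["contrast_BD"] == pytest.approx(
            summary["contrast_BD"])
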