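"""In-silico sensory-preconditioning experiment.

Builds and executes the four-stage protocol on an assembled model:

1. **Naming** - each of the four stimuli (A, B, C, D) is shown and
   labeled; each labeling event is one supervised training step of the
   perception layer.
2. **Preconditioning** - the neutral pairs A-then-B and C-then-D are
   presented back to back (no gap between the two members), repeatedly,
   with >30 s between trials; the ring's STDP learns the successions.
3. **Conditioning** - B is presented with unit reward pulses 1, 4 and
   7 s after onset; D is presented unrewarded.
4. **Probe** - A, B, C and D are each presented unrewarded with all
   learning frozen; the dopaminergic activity z is the readout.
   Transitive reward inference shows up as z(A-probe) > z(C-probe) and
   z(B-probe) > z(D-probe).

Events are a pure function of the configuration; all randomness in a
run comes from the observation noise stream seeded by ``cfg.seed``.
Traces are long-format records (t, signal, value).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, fields, replace

import numpy as np
import pandas as pd
import yaml

from .models import (ModelAState, ModelBState, make_model_a, make_model_b,
                     model_a_step, model_b_step)
from .perception import (Vocabulary, calibrate_theta_h, learn_label,
                         make_prototypes, observe, register_pattern)

__all__ = ["ProtocolEvent", "ExperimentConfig", "TraceRecord",
           "default_config", "load_config", "build_model", "build_protocol",
           "run_protocol", "probe_summary", "events_to_jsonl",
           "events_from_jsonl"]

logger = logging.getLogger("ringsim")


@dataclass(frozen=True)
class ProtocolEvent:
    """A timed event: half-open step interval [t_start, t_end), a kind
    in {show, label, reward, probe_marker} and an optional stimulus
    index."""

    t_start: int
    t_end: int
    kind: str
    stimulus: int | None = None

    def __post_init__(self) -> None:
        if self.t_start > self.t_end:
            raise ValueError("t_start must be <= t_end")
        if self.kind not in ("show", "label", "reward", "probe_marker"):
            raise ValueError(f"unknown event kind {self.kind!r}")


@dataclass(frozen=True)
class TraceRecord:
    t: int
    signal: str
    value: float


@dataclass(frozen=True)
class ExperimentConfig:
    """Full parameterization of a run; defaults follow the in-silico
    protocol (times in seconds, 1 step = dt seconds)."""

    K: int = 4
    ell: int = 64
    sigma_noise: float = 0.05
    lam: float = 0.8
    l: float = 0.1
    theta_H: float | None = None      # None = calibrate after naming (Oja)
    h: tuple = (1, -1)                # ring STDP polarity
    tau_w: float = 1.0
    alpha: float = 0.2
    T: int = 10
    dt: float = 1.0
    seed: int = 0
    naming_reps: int = 5              # q supervised steps per stimulus
    precond_reps: int = 6
    pair_order: tuple = ((0, 1), (2, 3))   # (A,B) then (C,D)
    stimulus_duration_s: int = 10
    inter_trial_gap_s: int = 31
    conditioning_reps: int = 9
    reward_delays_s: tuple = (1, 4, 7)
    probe_reps: int = 3

    def __post_init__(self) -> None:
        if not set(self.reward_delays_s) <= {1, 4, 7}:
            raise ValueError("reward_delays_s must be a subset of {1, 4, 7}")
        if self.inter_trial_gap_s <= 30:
            raise ValueError("inter-trial gap must exceed 30 s")
        if not 6 <= self.precond_reps <= 7:
            raise ValueError("precond_reps must be 6 or 7")
        if not 3 <= self.conditioning_reps <= 9:
            raise ValueError("conditioning_reps must be in 3..9")
        if self.stimulus_duration_s < 1 or self.naming_reps < 1:
            raise ValueError("durations and repetition counts must be >= 1")
        if self.K < 4:
            raise ValueError("the protocol needs at least 4 stimuli")

    @property
    def steps_per_second(self) -> float:
        return 1.0 / self.dt


def default_config(model: str = "B", **overrides) -> ExperimentConfig:
    """Protocol defaults per model: one naming step for the Oja-based
    Model A, five for the BCM-based Model B."""
    cfg = ExperimentConfig(naming_reps=1 if model.upper() == "A" else 5)
    return replace(cfg, **overrides) if overrides else cfg


def load_config(path) -> ExperimentConfig:
    """Read a YAML config mirroring ExperimentConfig field-for-field;
    unknown keys are rejected."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in fields(ExperimentConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for key in ("h", "reward_delays_s"):
        if key in raw:
            raw[key] = tuple(raw[key])
    if "pair_order" in raw:
        raw["pair_order"] = tuple(tuple(p) for p in raw["pair_order"])
    return ExperimentConfig(**raw)


def build_model(kind: str, cfg: ExperimentConfig):
    kind = kind.upper()
    if kind == "A":
        model = make_model_a(cfg.K, cfg.ell, cfg.lam, cfg.l, cfg.dt,
                             ring_h=cfg.h, tau_w=cfg.tau_w)
        if cfg.theta_H is not None:
            model.layer.theta_H = cfg.theta_H
        return model
    if kind == "B":
        return make_model_b(cfg.K, cfg.ell, cfg.lam, cfg.l, cfg.dt,
                            ring_h=cfg.h, tau_w=cfg.tau_w, T=cfg.T,
                            alpha=cfg.alpha)
    raise ValueError("model must be 'A' or 'B'")


def _steps(cfg: ExperimentConfig, seconds: float) -> int:
    return max(1, int(round(seconds / cfg.dt)))


def build_protocol(cfg: ExperimentConfig) -> list[ProtocolEvent]:
    """Emit the full deterministic event list for a run (pure function
    of cfg, no hidden randomness)."""
    dur = _steps(cfg, cfg.stimulus_duration_s)
    gap = _steps(cfg, cfg.inter_trial_gap_s)
    events: list[ProtocolEvent] = []
    t = gap  # initial settling period

    # stage 1: naming -- each stimulus shown with a one-step label event
    # at onset, naming_reps times
    for s in range(4):
        for _ in range(cfg.naming_reps):
            events.append(ProtocolEvent(t, t + dur, "show", s))
            events.append(ProtocolEvent(t, t + 1, "label", s))
            t += dur + gap

    # stage 2: preconditioning -- paired successions, the second member
    # starting the step after the first ends
    for _ in range(cfg.precond_reps):
        for (first, second) in cfg.pair_order:
            events.append(ProtocolEvent(t, t + dur, "show", first))
            events.append(ProtocolEvent(t + dur, t + 2 * dur, "show", second))
            t += 2 * dur + gap

    # stage 3: conditioning -- B with reward pulses, D unrewarded
    b, d = cfg.pair_order[0][1], cfg.pair_order[1][1]
    for _ in range(cfg.conditioning_reps):
        events.append(ProtocolEvent(t, t + dur, "show", b))
        for delay in cfg.reward_delays_s:
            t_r = t + _steps(cfg, delay)
            events.append(ProtocolEvent(t_r, t_r + 1, "reward", None))
        t += dur + gap
        events.append(ProtocolEvent(t, t + dur, "show", d))
        t += dur + gap

    # stage 4: probes -- unrewarded, learning frozen
    for _ in range(cfg.probe_reps):
        for s in (cfg.pair_order[0][0], b, cfg.pair_order[1][0], d):
            events.append(ProtocolEvent(t, t + dur, "show", s))
            events.append(ProtocolEvent(t, t + dur + 2, "probe_marker", s))
            t += dur + gap
    return events


def _naming_end(events) -> int:
    labels = [e.t_end for e in events if e.kind == "label"]
    return max(labels) if labels else 0


def run_protocol(model, events: list[ProtocolEvent], cfg: ExperimentConfig,
                 protos=None) -> pd.DataFrame:
    """Execute ``events`` on ``model`` step by step.

    Returns a long-format trace DataFrame with columns (t, signal,
    value); signals are v_<name>, r_<name>, z and, for Model B,
    theta_<name>.  Probe windows run with learning frozen.  The run is
    fully reproducible from (cfg, events).
    """
    starts = [e.t_start for e in events]
    if starts != sorted(starts):
        raise ValueError("events must be sorted by t_start")
    rng = np.random.default_rng(cfg.seed)
    if protos is None:
        protos = make_prototypes(cfg.K, cfg.ell, cfg.sigma_noise, cfg.seed)
    vocab = Vocabulary(capacity=cfg.K)
    for p in protos:
        register_pattern(vocab, p.name)
    names = vocab.names
    is_b = isinstance(model, ModelBState)
    naming_end = _naming_end(events)
    horizon = (max(e.t_end for e in events) + 15) if events else 0

    shows = [e for e in events if e.kind == "show"]
    labels = {e.t_start: e.stimulus for e in events if e.kind == "label"}
    reward_steps = {t for e in events if e.kind == "reward"
                    for t in range(e.t_start, e.t_end)}
    probe_steps = {t for e in events if e.kind == "probe_marker"
                   for t in range(e.t_start, e.t_end)}

    show_at = {}
    for e in shows:
        for t in range(e.t_start, e.t_end):
            show_at[t] = e.stimulus

    records: list[TraceRecord] = []
    calibrated = cfg.theta_H is not None
    stage_logged = set()
    for t in range(horizon):
        stim = show_at.get(t)
        frame = (observe(protos[stim], rng) if stim is not None
                 else observe(None, rng, ell=cfg.ell,
                              sigma_noise=cfg.sigma_noise))
        if t in labels and t not in probe_steps:
            model.layer = learn_label(model.layer, frame, labels[t], cfg.dt)
        if (not calibrated and not is_b and t >= naming_end):
            model.layer = calibrate_theta_h(model.layer, protos)
            calibrated = True
            logger.info("calibrated theta_H = %.4f", model.layer.theta_H)
        learning_on = t not in probe_steps
        if is_b:
            model, info = model_b_step(model, frame, t in reward_steps,
                                       learning_on)
        else:
            model, info = model_a_step(model, frame, t in reward_steps,
                                       learning_on)
        for k, name in enumerate(names):
            records.append(TraceRecord(t, f"v_{name}", float(info["v"][k])))
            records.append(TraceRecord(t, f"r_{name}", float(info["r"][k])))
            if is_b:
                records.append(TraceRecord(t, f"theta_{name}",
                                           float(info["theta"][k])))
        records.append(TraceRecord(t, "z", float(info["z"])))
        if t % 500 == 0 and t not in stage_logged:
            stage_logged.add(t)
            S_norm = float(np.linalg.norm(model.ring.S))
            logger.info("t=%d |S|=%.3f", t, S_norm)
    return pd.DataFrame([(r.t, r.signal, r.value) for r in records],
                        columns=["t", "signal", "value"])


def probe_summary(traces: pd.DataFrame, events: list[ProtocolEvent],
                  names=("A", "B", "C", "D")) -> dict:
    """Peak z inside each probe window per stimulus, plus the transitive
    contrasts z(A)-z(C) and z(B)-z(D)."""
    probes = [e for e in events if e.kind == "probe_marker"]
    if not probes:
        raise ValueError("no probe windows in the event list")
    z = traces[traces.signal == "z"].set_index("t")["value"]
    peaks: dict[str, float] = {}
    for e in probes:
        name = names[e.stimulus]
        window = z.loc[e.t_start:e.t_end - 1]
        peak = float(window.max()) if len(window) else 0.0
        peaks[name] = max(peaks.get(name, -np.inf), peak)
    out = {f"peak_z_{n}": peaks.get(n, 0.0) for n in names}
    out["contrast_AC"] = out["peak_z_A"] - out["peak_z_C"]
    out["contrast_BD"] = out["peak_z_B"] - out["peak_z_D"]
    return out


def events_to_jsonl(events) -> str:
    return "\n".join(json.dumps(
        {"t_start": e.t_start, "t_end": e.t_end, "kind": e.kind,
         "stimulus": e.stimulus}) for e in events)


def events_from_jsonl(text: str) -> list[ProtocolEvent]:
    return [ProtocolEvent(**json.loads(line))
            for line in text.splitlines() if line.strip()]
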