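"""End-to-end assemblies: Ring Model A and Ring Model B.

Model A: Oja perception layer + ring + a single reward neuron z with a
fixed self-connection ``w_zz = lam`` and STDP-learned input weights
``wz`` from every ring neuron.  A delivered reward clamps z to 1 that
step; STDP then potentiates wz for ring neurons active the previous
step, so a conditioned stimulus comes to drive z to 1 on its own.
Because the reward link is LTP-only by default, Model A cannot
*unlearn* a reward: omitting the reward leaves wz untouched.

Model B: BCM perception layer + ring + the temporal-difference
circuit.  Every ring neuron feeds a delay chain (first slot mirrors
the ring activity) and the dopaminergic unit z reports the prediction
error, so associations both form under reward and extinguish under
reward omission.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .core import kappa, sigma_l
from .perception import (HebbianLayer, StimulusPrototype, make_layer, observe,
                         recognize, learn_label)
from .plasticity import BCMParams, OjaParams, STDPParams
from .ring import RingState, make_ring, ring_learn, ring_step
from .tdl import TDLState, collector, dopamine, make_tdl, shift_chains, tdl_learn

__all__ = ["ModelAState", "ModelBState", "make_model_a", "make_model_b",
           "model_a_step", "model_b_step", "run_conditioning",
           "run_extinction", "checkpoint", "restore"]


@dataclass
class ModelAState:
    layer: HebbianLayer
    ring: RingState
    wz: np.ndarray          # raw reward-link weights r -> z (STDP-learned)
    z: float
    z_prev: float
    ring_p: STDPParams      # polarity/time constant of ring learning
    wz_p: STDPParams        # polarity of the reward link (LTP-only default)
    l: float
    dt: float


@dataclass
class ModelBState:
    layer: HebbianLayer
    ring: RingState
    tdl: TDLState
    ring_p: STDPParams
    l: float
    dt: float


def make_model_a(K: int, ell: int, lam: float = 0.8, l: float = 0.1,
                 dt: float = 1.0, ring_h=(1, -1), wz_h=(1, 0),
                 tau_w: float = 1.0, oja: OjaParams | None = None) -> ModelAState:
    return ModelAState(
        layer=make_layer(K, ell, rule="oja", params=oja or OjaParams(tau_w=tau_w)),
        ring=make_ring(K, lam),
        wz=np.zeros(K), z=0.0, z_prev=0.0,
        ring_p=STDPParams(h=tuple(ring_h), tau_w=tau_w),
        wz_p=STDPParams(h=tuple(wz_h), tau_w=tau_w),
        l=l, dt=dt)


def make_model_b(K: int, ell: int, lam: float = 0.8, l: float = 0.1,
                 dt: float = 1.0, ring_h=(1, -1), tau_w: float = 1.0,
                 T: int = 10, alpha: float = 0.2,
                 bcm: BCMParams | None = None) -> ModelBState:
    return ModelBState(
        layer=make_layer(K, ell, rule="bcm", params=bcm or BCMParams(tau_w=tau_w)),
        ring=make_ring(K, lam),
        tdl=make_tdl(K, T, alpha),
        ring_p=STDPParams(h=tuple(ring_h), tau_w=tau_w),
        l=l, dt=dt)


def model_a_step(state: ModelAState, frame, reward_on: bool = False,
                 learning_on: bool = True):
    """One Model-A step.

    Recognize the frame, drive the ring with the binary recognition
    vector, then update the reward neuron

        z' = sigma_l(lam * z + kappa(wz) . r + reward),

    clamped to 1 whenever a reward is present.  With learning on, the
    ring weights and the reward link wz both take reduced-STDP updates
    (post = z, pre = r for the link).  Returns (state, info) where
    info carries the step's v, r and z.
    """
    v = recognize(state.layer, frame)
    ring = ring_step(state.ring, v, state.l)
    drive = state.ring.lam * state.z + float(kappa(state.wz) @ ring.r_now)
    if reward_on:
        z_new = 1.0
    else:
        z_new = float(sigma_l(drive, state.l))
    wz = state.wz
    if learning_on:
        ring = ring_learn(ring, state.ring_p, state.dt)
        h1, h2 = state.wz_p.h
        wz = wz + (state.dt / state.wz_p.tau_w) * (
            h1 * z_new * ring.r_prev + h2 * state.z * ring.r_now)
    new = ModelAState(layer=state.layer, ring=ring, wz=wz,
                      z=z_new, z_prev=state.z,
                      ring_p=state.ring_p, wz_p=state.wz_p,
                      l=state.l, dt=state.dt)
    info = {"v": v, "r": ring.r_now.copy(), "z": z_new}
    return new, info


def model_b_step(state: ModelBState, frame, reward_on: bool = False,
                 learning_on: bool = True):
    """One Model-B step: recognize -> ring -> chains -> collector ->
    dopamine -> (learn).  Returns (state, info) with the step's v, r,
    z, y and the BCM thresholds."""
    v = recognize(state.layer, frame)
    ring = ring_step(state.ring, v, state.l)
    tdl = shift_chains(state.tdl, ring.r_now)
    tdl.reward = 1.0 if reward_on else 0.0
    tdl.y = collector(tdl)
    tdl.z = dopamine(tdl)
    if learning_on:
        ring = ring_learn(ring, state.ring_p, state.dt)
        tdl = tdl_learn(tdl)
    new = ModelBState(layer=state.layer, ring=ring, tdl=tdl,
                      ring_p=state.ring_p, l=state.l, dt=state.dt)
    info = {"v": v, "r": ring.r_now.copy(), "z": tdl.z, "y": tdl.y,
            "theta": state.layer.theta.copy()}
    return new, info


def _model_step(model, frame, reward_on, learning_on):
    if isinstance(model, ModelAState):
        return model_a_step(model, frame, reward_on, learning_on)
    return model_b_step(model, frame, reward_on, learning_on)


def _present(model, proto: StimulusPrototype, rng, duration, reward_steps,
             learning_on, tail):
    """Present one stimulus for ``duration`` steps (reward pulses at the
    given onset offsets), then run ``tail`` background steps.  Returns
    the model and the z trace."""
    ell = len(proto.mu)
    zs = []
    for t in range(duration + tail):
        if t < duration:
            frame = observe(proto, rng)
        else:
            frame = observe(None, rng, ell=ell, sigma_noise=proto.sigma_noise)
        model, info = _model_step(model, frame, t in reward_steps, learning_on)
        zs.append(info["z"])
    return model, np.asarray(zs)


def _flush_tail(model) -> int:
    """Inter-trial steps needed for the ring trace to extinguish and the
    delay chains to empty (mirrors the protocol's >30 s gap)."""
    lam, l = model.ring.lam, model.l
    decay = int(np.ceil(np.log(l) / np.log(lam))) if lam > 0 else 1
    T = model.tdl.T if isinstance(model, ModelBState) else 0
    return decay + T + 1


def run_conditioning(model, proto: StimulusPrototype, n_trials: int,
                     rng: np.random.Generator, duration: int = 10,
                     reward_delays=(1, 4, 7), tail: int | None = None,
                     probe_each: bool = True):
    """Repeated conditioning trials pairing ``proto`` with delayed unit
    reward pulses.

    After each trial (optionally) probes the stimulus with learning
    frozen and no reward, recording the dopaminergic activity at
    stimulus onset and its peak over the probe window.  Returns the
    model and a dict of per-trial arrays.
    """
    if tail is None:
        tail = _flush_tail(model)
    onset_z, peak_z = [], []
    for _ in range(n_trials):
        model, _ = _present(model, proto, rng, duration,
                            set(reward_delays), True, tail)
        if probe_each:
            model, zp = _present(model, proto, rng, duration, set(), False, tail)
            onset_z.append(zp[0])
            peak_z.append(float(np.max(zp)))
    return model, {"onset_z": np.asarray(onset_z), "peak_z": np.asarray(peak_z)}


def run_extinction(model, proto: StimulusPrototype, n_trials: int,
                   rng: np.random.Generator, duration: int = 10,
                   tail: int | None = None):
    """Repeated unrewarded presentations with learning on; probes (frozen,
    unrewarded) after each trial.  Returns the model and per-trial peak
    probe z."""
    if tail is None:
        tail = _flush_tail(model)
    peaks = []
    for _ in range(n_trials):
        model, _ = _present(model, proto, rng, duration, set(), True, tail)
        model, zp = _present(model, proto, rng, duration, set(), False, tail)
        peaks.append(float(np.max(zp)))
    return model, np.asarray(peaks)


def checkpoint(model) -> str:
    """Serialize a model state (all matrices, thresholds, parameters) to
    a JSON string for resumable runs."""
    def arr(a):
        return np.asarray(a).tolist()
    if isinstance(model, ModelAState):
        d = {"kind": "A",
             "H": arr(model.layer.H), "theta": arr(model.layer.theta),
             "theta_H": model.layer.theta_H, "c": model.layer.c,
             "S": arr(model.ring.S), "lam": model.ring.lam,
             "r_now": arr(model.ring.r_now), "r_prev": arr(model.ring.r_prev),
             "wz": arr(model.wz), "z": model.z, "z_prev": model.z_prev,
             "ring_h": list(model.ring_p.h), "wz_h": list(model.wz_p.h),
             "tau_w": model.ring_p.tau_w, "l": model.l, "dt": model.dt}
    else:
        d = {"kind": "B",
             "H": arr(model.layer.H), "theta": arr(model.layer.theta),
             "c": model.layer.c,
             "S": arr(model.ring.S), "lam": model.ring.lam,
             "r_now": arr(model.ring.r_now), "r_prev": arr(model.ring.r_prev),
             "x": arr(model.tdl.x), "x_prev": arr(model.tdl.x_prev),
             "w": arr(model.tdl.w), "alpha": model.tdl.alpha,
             "reward": model.tdl.reward, "y": model.tdl.y, "zz": model.tdl.z,
             "ring_h": list(model.ring_p.h),
             "tau_w": model.ring_p.tau_w, "l": model.l, "dt": model.dt}
    if not np.isfinite(d.get("theta_H", 0.0)):
        d["theta_H"] = None
    return json.dumps(d)


def restore(text: str):
    """Rebuild a model state from a ``checkpoint`` JSON string."""
    d = json.loads(text)
    A = lambda k: np.asarray(d[k], float)
    ring = RingState(S=A("S"), lam=d["lam"], r_now=A("r_now"),
                     r_prev=A("r_prev"))
    if d["kind"] == "A":
        layer = HebbianLayer(H=A("H"), rule="oja", params=OjaParams(tau_w=d["tau_w"]),
                             theta=A("theta"),
                             theta_H=np.inf if d["theta_H"] is None else d["theta_H"],
                             c=d["c"])
        return ModelAState(layer=layer, ring=ring, wz=A("wz"), z=d["z"],
                           z_prev=d["z_prev"],
                           ring_p=STDPParams(h=tuple(d["ring_h"]), tau_w=d["tau_w"]),
                           wz_p=STDPParams(h=tuple(d["wz_h"]), tau_w=d["tau_w"]),
                           l=d["l"], dt=d["dt"])
    layer = HebbianLayer(H=A("H"), rule="bcm", params=BCMParams(tau_w=d["tau_w"]),
                         theta=A("theta"), c=d["c"])
    tdl = TDLState(x=A("x"), x_prev=A("x_prev"), w=A("w"), alpha=d["alpha"],
                   reward=d["reward"], y=d["y"], z=d["zz"])
    return ModelBState(layer=layer, ring=ring, tdl=tdl,
                       ring_p=STDPParams(h=tuple(d["ring_h"]), tau_w=d["tau_w"]),
                       l=d["l"], dt=d["dt"])
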