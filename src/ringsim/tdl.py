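"""Temporal-difference reward circuit: delay chains, collector, dopamine.

Every ring neuron feeds a tapped delay line ("temporal chain") of T
slots; the first slot mirrors the ring activity and the content shifts
one slot per step.  A collector neuron sums the weighted one-step
*differences* of all chain activities,

    y(t) = sum_ij w_ij (x_ij(t) - x_ij(t-1)),

and the dopaminergic unit reports the prediction error

    z(t) = r(t) + y(t),

where r is the reward-neuron activity (1 during a reward pulse).  The
chain weights learn with

    w_ij(t+1) = w_ij(t) + alpha * x_ij(t-1) * z(t),

which is the classical temporal-difference update over a complete
serial-compound representation of each stimulus: unexpected rewards
(positive z) push value earlier in time, omitted expected rewards
(negative z) extinguish it.  z is deliberately not clipped - extinction
requires negative prediction errors.

The fixed collector->dopamine and reward->dopamine connections are 1
and never learned.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["TDLState", "make_tdl", "shift_chains", "collector", "dopamine",
           "tdl_learn", "tdl_step", "tdl_trial"]


@dataclass
class TDLState:
    """Chain activities x (K x T), their previous values, chain weights
    w, the learning rate alpha, and the current reward/collector/
    dopamine activities."""

    x: np.ndarray
    x_prev: np.ndarray
    w: np.ndarray
    alpha: float
    reward: float = 0.0
    y: float = 0.0
    z: float = 0.0

    @property
    def K(self) -> int:
        return self.x.shape[0]

    @property
    def T(self) -> int:
        return self.x.shape[1]


def make_tdl(K: int, T: int = 10, alpha: float = 0.2) -> TDLState:
    if K < 1 or T < 1:
        raise ValueError("K and T must be >= 1")
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    return TDLState(x=np.zeros((K, T)), x_prev=np.zeros((K, T)),
                    w=np.zeros((K, T)), alpha=alpha)


def shift_chains(state: TDLState, ring_activity) -> TDLState:
    """Advance every delay chain one slot.

    Slot 1 takes the current ring activity; slot j+1 takes what slot j
    held; the oldest slot's content drops off the end.
    """
    r = np.asarray(ring_activity, dtype=float)
    if r.shape != (state.K,):
        raise ValueError(f"ring_activity must have length {state.K}")
    x_new = np.empty_like(state.x)
    x_new[:, 0] = r
    x_new[:, 1:] = state.x[:, :-1]
    return TDLState(x=x_new, x_prev=state.x.copy(), w=state.w.copy(),
                    alpha=state.alpha, reward=state.reward,
                    y=state.y, z=state.z)


def collector(state: TDLState) -> float:
    """Collector activity: weighted sum of one-step chain differences."""
    return float(np.sum(state.w * (state.x - state.x_prev)))


def dopamine(state: TDLState) -> float:
    """Prediction-error signal z = reward + y (unclipped; may be
    negative during extinction)."""
    return float(state.reward + state.y)


def tdl_learn(state: TDLState) -> TDLState:
    """TD weight update ``w += alpha * x(t-1) * z(t)`` on every chain
    slot.  The fixed collector/reward links are not represented in w
    and remain 1."""
    w_new = state.w + state.alpha * state.x_prev * state.z
    return TDLState(x=state.x.copy(), x_prev=state.x_prev.copy(), w=w_new,
                    alpha=state.alpha, reward=state.reward,
                    y=state.y, z=state.z)


def tdl_step(state: TDLState, ring_activity, reward: float,
             learn: bool = True) -> TDLState:
    """One full circuit step: shift -> collector -> dopamine -> learn."""
    state = shift_chains(state, ring_activity)
    state.reward = float(reward)
    state.y = collector(state)
    state.z = dopamine(state)
    if learn:
        state = tdl_learn(state)
    return state


def tdl_trial(state: TDLState, stimulus_index: int, delay: int,
              rewarded: bool, duration: int = 1, tail: int | None = None,
              learn: bool = True):
    """One conditioning trial on a single stimulus.

    The stimulus drives its ring line at 1 for ``duration`` steps from
    trial onset; if ``rewarded``, a one-step unit reward pulse arrives
    ``delay`` steps after onset.  The trial runs for
    ``duration + tail`` steps (``tail`` defaults to T + 2 so the chain
    fully empties).  Returns the final state and the per-step z trace.
    """
    if delay >= state.T:
        raise ValueError("reward delay must be < chain length T")
    if tail is None:
        tail = state.T + 2
    zs = []
    for t in range(duration + tail):
        ring = np.zeros(state.K)
        if t < duration:
            ring[stimulus_index] = 1.0
        reward = 1.0 if (rewarded and t == delay) else 0.0
        state = tdl_step(state, ring, reward, learn=learn)
        zs.append(state.z)
    return state, np.asarray(zs)
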