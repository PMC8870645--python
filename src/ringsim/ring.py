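"""The Ring: a K-neuron fully recurrent network for temporal succession.

Each neuron fires selectively for one stimulus.  The connectivity
matrix S has a fixed diagonal self-connection ``lam`` in [0, 1) that
prolongs activity geometrically after a stimulus disappears
(``r_i(t + tau) = lam**tau``), while the off-diagonal entries are
learned with the reduced STDP rule and therefore come to encode
temporal succession: if B reliably follows A within a bounded delay,
the A->B weight accumulates at least ``(dt/tau_w) * lam**T2`` per
paired presentation and eventually saturates the read-time clip at 1,
after which presenting A alone ignites B one step later.

Raw weights are stored unclipped; the dynamics only ever see
``kappa(S)`` (entries clipped into [0, 1]).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import kappa, sigma_l
from .plasticity import STDPParams, stdp_reduced_update

__all__ = ["RingState", "PrecedenceSpec", "make_ring", "ring_step",
           "ring_learn", "present_pair", "settle"]


@dataclass
class RingState:
    """Connectivity and the current/previous activity of the ring.

    ``S`` holds raw (unclipped) weights with diagonal fixed at ``lam``;
    ``r_now`` and ``r_prev`` are the activities at the current and
    previous step, each in [0, 1].
    """

    S: np.ndarray
    lam: float
    r_now: np.ndarray
    r_prev: np.ndarray

    @property
    def K(self) -> int:
        return len(self.r_now)


@dataclass(frozen=True)
class PrecedenceSpec:
    """A succession A -> B: stimulus ``j`` follows stimulus ``i`` after a
    delay drawn from the window [T1, T2] (in steps)."""

    i: int
    j: int
    T1: int = 1
    T2: int = 1

    def __post_init__(self) -> None:
        if not 1 <= self.T1 <= self.T2:
            raise ValueError("delay window requires 1 <= T1 <= T2")
        if self.i == self.j:
            raise ValueError("predecessor and successor must differ")


def make_ring(K: int, lam: float = 0.8) -> RingState:
    """Quiescent K-neuron ring with self-decay ``lam`` and zero
    cross-weights."""
    if not 0.0 <= lam < 1.0:
        raise ValueError("lam must be in [0, 1)")
    S = np.zeros((K, K))
    np.fill_diagonal(S, lam)
    return RingState(S=S, lam=lam, r_now=np.zeros(K), r_prev=np.zeros(K))


def ring_step(state: RingState, input_drive, l: float = 0.1) -> RingState:
    """Advance the ring one step: ``r' = sigma_l(kappa(S) r + drive)``.

    The previous activity is retained for the next learning call.  S is
    unchanged.
    """
    drive = np.asarray(input_drive, dtype=float)
    if drive.shape != state.r_now.shape:
        raise ValueError(f"input_drive must have length {state.K}")
    r_new = sigma_l(kappa(state.S) @ state.r_now + drive, l)
    return RingState(S=state.S, lam=state.lam,
                     r_now=np.asarray(r_new, float), r_prev=state.r_now.copy())


def ring_learn(state: RingState, p: STDPParams, dt: float = 1.0) -> RingState:
    """Reduced-STDP update of every off-diagonal weight.

    Entry S[j, i] (pre i -> post j) moves by
    ``(dt/tau_w) * (h1 * r_j(t) r_i(t-1) + h2 * r_j(t-1) r_i(t))``.
    Self-connections are excluded: the diagonal stays at ``lam``.  Raw
    weights may leave [0, 1]; clipping happens only at read time.
    """
    r, rp = state.r_now, state.r_prev
    S_new = stdp_reduced_update(
        state.S, r[:, None], rp[:, None], r[None, :], rp[None, :], p, dt)
    np.fill_diagonal(S_new, state.lam)
    return RingState(S=S_new, lam=state.lam,
                     r_now=r.copy(), r_prev=rp.copy())


def settle(state: RingState, l: float = 0.1, max_steps: int = 1000) -> RingState:
    """Run zero-input steps (no learning) until the ring is quiescent.

    With lam < 1 and l > 0 an isolated trace extinguishes within
    ``ceil(log l / log lam)`` steps; ``max_steps`` guards against
    learned self-sustaining loops.
    """
    for _ in range(max_steps):
        if not state.r_now.any():
            return state
        state = ring_step(state, np.zeros(state.K), l)
    return state


def present_pair(state: RingState, spec: PrecedenceSpec, p: STDPParams,
                 l: float = 0.1, dt: float = 1.0,
                 rng: np.random.Generator | None = None) -> RingState:
    """One paired presentation: drive neuron ``i``, then neuron ``j``
    after a delay drawn from [T1, T2], learning at every step of the
    pairing.

    Learning is applied through the step at which the successor fires;
    the ring is then settled back to quiescence without learning, so
    that successive presentations are independent events, as in the
    convergence argument for succession learning.  Each presentation
    increments S[j, i] by at least ``(dt/tau_w) * lam**T2``.
    """
    if spec.i >= state.K or spec.j >= state.K:
        raise ValueError("stimulus index outside the ring")
    if spec.T1 == spec.T2:
        delay = spec.T1
    else:
        if rng is None:
            raise ValueError("rng required when T1 < T2")
        delay = int(rng.integers(spec.T1, spec.T2 + 1))
    for t in range(delay + 1):
        drive = np.zeros(state.K)
        if t == 0:
            drive[spec.i] = 1.0
        if t == delay:
            drive[spec.j] = 1.0
        state = ring_step(state, drive, l)
        state = ring_learn(state, p, dt)
    return settle(state, l)
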