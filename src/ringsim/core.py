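"""Elementary firing-rate neuron dynamics shared by every other module.

Activities are non-negative firing rates (dimensionless after
normalization).  The clipped-linear activation ``sigma_l`` maps a net
input onto [0, 1]: values below the silence threshold ``l`` are cut to
zero, values above 1 saturate.  ``kappa`` is the read-time weight
control that confines effective synaptic weights to [0, 1] while the
raw stored weights may drift outside that interval during learning.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SimClock",
    "sigma_l",
    "kappa",
    "heaviside",
    "linear_rate",
    "euler_step",
]


@dataclass
class SimClock:
    """Discrete simulation clock: ``step`` counts ticks, ``dt`` is the
    real time (seconds) represented by one tick."""

    step: int = 0
    dt: float = 1.0

    def __post_init__(self) -> None:
        if self.step < 0:
            raise ValueError("step must be >= 0")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")

    def tick(self) -> int:
        self.step += 1
        return self.step

    @property
    def time(self) -> float:
        return self.step * self.dt


def sigma_l(x, l: float):
    """Clipped-linear activation.

    Returns 1 where ``x > 1``, ``x`` where ``l <= x <= 1`` and 0 where
    ``x < l``.  Applied elementwise to arrays.  ``l`` must lie in
    [0, 1).
    """
    if not 0.0 <= l < 1.0:
        raise ValueError(f"silence threshold l must be in [0, 1), got {l}")
    x_arr = np.asarray(x, dtype=float)
    out = np.where(x_arr > 1.0, 1.0, np.where(x_arr < l, 0.0, x_arr))
    if np.isscalar(x) or x_arr.ndim == 0:
        return float(out)
    return out


def kappa(W):
    """Read-time weight control: clip every entry into [0, 1].

    Equivalent to ``sigma_l`` with ``l = 0`` applied entrywise.  The
    input is never mutated; callers receive an independent clipped
    array.
    """
    W_arr = np.asarray(W, dtype=float)
    if not np.all(np.isfinite(W_arr)):
        raise ValueError("kappa requires finite weights")
    return np.clip(W_arr, 0.0, 1.0)


def heaviside(x, theta_H: float):
    """Step readout: 1 where ``x >= theta_H`` else 0.

    The boundary ``x == theta_H`` counts as recognized (closed
    recognition set).
    """
    if not np.isfinite(theta_H):
        # +inf threshold = readout disabled (nothing recognized)
        x_arr = np.asarray(x, dtype=float)
        out = np.zeros_like(x_arr)
    else:
        x_arr = np.asarray(x, dtype=float)
        out = np.where(x_arr >= theta_H, 1.0, 0.0)
    if np.isscalar(x) or x_arr.ndim == 0:
        return float(out)
    return out


def linear_rate(w, u, f=None) -> float:
    """Single-neuron firing rate ``v = f(w . u)``.

    ``f`` defaults to the identity.
    """
    w_arr = np.asarray(w, dtype=float)
    u_arr = np.asarray(u, dtype=float)
    if w_arr.shape != u_arr.shape:
        raise ValueError(f"shape mismatch: {w_arr.shape} vs {u_arr.shape}")
    net = float(w_arr @ u_arr)
    return net if f is None else float(f(net))


def euler_step(state, derivative, dt: float):
    """One forward-Euler step: ``state + dt * derivative``."""
    if dt <= 0:
        raise ValueError("dt must be > 0")
    s = np.asarray(state, dtype=float)
    d = np.asarray(derivative, dtype=float)
    if s.shape != d.shape:
        raise ValueError(f"shape mismatch: {s.shape} vs {d.shape}")
    out = s + dt * d
    if np.isscalar(state) or s.ndim == 0:
        return float(out)
    return out
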