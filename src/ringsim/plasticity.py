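"""Rate-based plasticity rules: Oja, BCM, and a reduced STDP rule.

All three are pure update laws over a forward-Euler step of size
``dt``; the weight time constant ``tau_w`` sets the effective learning
rate ``dt / tau_w``.

The reduced STDP rule is a one-step discretization of the continuous
spike-timing window integral

    tau_w dw/dt = int_0^inf H(tau) v(t) u(t-tau) + H(-tau) v(t-tau) u(t) dtau

with an odd window H whose sign is the sign of tau: pre-before-post
potentiates (LTP), post-before-pre depresses (LTD).  The reduction
keeps only the one-step correlations,

    tau_w dw/dt = h1 * v(t) u(t-1) + h2 * v(t-1) u(t),

with h = (h1, h2), each in {-1, 0, 1}.  h = (1, -1) reproduces the
antisymmetric LTP/LTD pair; h = (1, 0) is LTP-only.
``stdp_integral_update`` evaluates the window integral by direct
quadrature and serves as the independent oracle for the reduced rule's
sign behavior.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "OjaParams",
    "BCMParams",
    "STDPParams",
    "STDPWindow",
    "oja_update",
    "bcm_update",
    "stdp_reduced_update",
    "stdp_window_H",
    "stdp_integral_update",
]


@dataclass(frozen=True)
class OjaParams:
    """Oja rule parameters: weight time constant and norm penalty."""

    tau_w: float = 1.0
    beta: float = 1.0

    def __post_init__(self) -> None:
        if self.tau_w <= 0 or self.beta <= 0:
            raise ValueError("tau_w and beta must be > 0")


@dataclass(frozen=True)
class BCMParams:
    """BCM rule parameters.

    ``tau_theta`` is the time constant of the sliding threshold, which
    relaxes toward the square of the post-synaptic rate; ``theta0`` is
    its initial value.
    """

    tau_w: float = 1.0
    tau_theta: float = 1.0
    theta0: float = 0.0

    def __post_init__(self) -> None:
        if self.tau_w <= 0 or self.tau_theta <= 0:
            raise ValueError("tau_w and tau_theta must be > 0")
        if self.theta0 < 0:
            raise ValueError("theta0 must be >= 0")


@dataclass(frozen=True)
class STDPParams:
    """Reduced-STDP parameters: the polarity pair h and tau_w."""

    h: tuple = (1, -1)
    tau_w: float = 1.0

    def __post_init__(self) -> None:
        if len(self.h) != 2 or any(int(c) not in (-1, 0, 1) for c in self.h):
            raise ValueError(f"h entries must be in {{-1, 0, 1}}, got {self.h}")
        if self.tau_w <= 0:
            raise ValueError("tau_w must be > 0")


@dataclass(frozen=True)
class STDPWindow:
    """Continuous STDP window H(tau) = sign(tau) * a / max(|tau|, eps).

    Odd in tau, zero beyond the physiological cutoff ``tau_max``
    (default 50 ms), zero at tau = 0.  ``eps`` regularizes the 1/tau
    divergence near zero; choose it equal to the sampling spacing.
    """

    a: float = 1.0 / 40.0
    tau_max: float = 50.0
    eps: float = 1.0

    def __post_init__(self) -> None:
        if self.a <= 0 or self.tau_max <= 0 or self.eps <= 0:
            raise ValueError("a, tau_max and eps must be > 0")


def oja_update(w, v: float, u, p: OjaParams, dt: float):
    """One Oja step: ``w + (dt/tau_w) * (v*u - beta*v^2*w)``.

    The quadratic decay bounds the weight norm; with beta = 1 and
    self-generated v = w.u on stationary zero-mean input, w converges
    to a unit-norm leading eigenvector of the input second-moment
    matrix.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    w_arr = np.asarray(w, dtype=float)
    u_arr = np.asarray(u, dtype=float)
    if w_arr.shape != u_arr.shape:
        raise ValueError(f"shape mismatch: {w_arr.shape} vs {u_arr.shape}")
    return w_arr + (dt / p.tau_w) * (v * u_arr - p.beta * v * v * w_arr)


def bcm_update(w, theta: float, v: float, u, p: BCMParams, dt: float):
    """One synchronous BCM step.

    Returns ``(w', theta')`` where both updates use the pre-update
    values:

        w'     = w + (dt/tau_w) * v * u * (v - theta)
        theta' = theta + (dt/tau_theta) * (v^2 - theta)

    Post-synaptic rates above the sliding threshold potentiate, below
    it depress; theta chases v^2, which stabilizes the layer.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    w_arr = np.asarray(w, dtype=float)
    u_arr = np.asarray(u, dtype=float)
    if w_arr.shape != u_arr.shape:
        raise ValueError(f"shape mismatch: {w_arr.shape} vs {u_arr.shape}")
    w_new = w_arr + (dt / p.tau_w) * v * u_arr * (v - theta)
    theta_new = theta + (dt / p.tau_theta) * (v * v - theta)
    return w_new, theta_new


def stdp_reduced_update(w, v_t, v_prev, u_t, u_prev, p: STDPParams, dt: float):
    """One reduced-STDP step on a scalar weight (broadcasts over arrays).

    ``w + (dt/tau_w) * (h1 * v(t) u(t-1) + h2 * v(t-1) u(t))`` with
    post-synaptic v and pre-synaptic u.  With h = (1, -1) this is the
    antisymmetric LTP/LTD rule; equal constant activities cancel
    exactly.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    h1, h2 = p.h
    delta = h1 * np.asarray(v_t, float) * np.asarray(u_prev, float) \
        + h2 * np.asarray(v_prev, float) * np.asarray(u_t, float)
    out = np.asarray(w, float) + (dt / p.tau_w) * delta
    if np.isscalar(w):
        return float(out)
    return out


def stdp_window_H(tau: float, win: STDPWindow) -> float:
    """Evaluate the continuous window H at lag ``tau`` (post minus pre).

    sign(tau) * a / max(|tau|, eps) inside the cutoff, 0 outside and at
    tau = 0.  Odd by construction: H(-tau) = -H(tau).
    """
    if tau == 0:
        return 0.0
    if abs(tau) > win.tau_max:
        return 0.0
    return float(np.sign(tau) * win.a / max(abs(tau), win.eps))


def stdp_integral_update(w: float, v_history, u_history, win: STDPWindow,
                         tau_w: float, dt: float) -> float:
    """Brute-force quadrature of the STDP window integral.

    ``v_history`` and ``u_history`` are post-/pre-synaptic rate traces
    sampled on the same grid with spacing ``dt``.  The update sums, over
    every sample time and every lag ``tau = k*dt`` in (0, tau_max],

        H(tau) * v(t) u(t - tau)  -  H(tau) * v(t - tau) u(t)

    (using oddness of H), scaled by ``dt^2 / tau_w`` (one dt for the
    lag quadrature, one for the time step).  Serves as the independent
    oracle for the reduced rule's sign behavior.
    """
    v = np.asarray(v_history, dtype=float)
    u = np.asarray(u_history, dtype=float)
    if v.shape != u.shape or v.ndim != 1:
        raise ValueError("histories must be 1-d and sampled on the same grid")
    n = len(v)
    k_max = int(np.floor(win.tau_max / dt))
    total = 0.0
    for k in range(1, k_max + 1):
        H_k = stdp_window_H(k * dt, win)
        if H_k == 0.0:
            continue
        # sum over t of v(t)u(t-k) and v(t-k)u(t)
        ltp = float(v[k:] @ u[:n - k])
        ltd = float(v[:n - k] @ u[k:])
        total += H_k * (ltp - ltd)
    return w + (dt * dt / tau_w) * total
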