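"""Synthetic perception front end.

Stands in for the ConvNet feature extractor and the speech-to-text
naming channel: each stimulus class is a fixed non-negative unit-norm
prototype feature vector, observed with additive Gaussian noise
(clipped at zero, since firing rates are non-negative).  Prototypes
are built on disjoint feature-support blocks and are therefore
mutually orthogonal, emulating the highly selective inferior-temporal
style features the architecture assumes.

On top sits a Hebbian classification layer ``v = H u`` trained by name
supervision: at a labeling event the labeled entry of v is clamped to
1 and each row of H is updated with the layer's rule (Oja or BCM);
unlabeled rows learn from their own, self-generated responses.  The
binary readout uses a Heaviside step: a fixed threshold ``theta_H``
for the Oja layer (calibrated after training, since a universal fixed
threshold is hard to pick for Oja responses), or a sliding per-class
threshold ``c * sqrt(theta_i)`` for the BCM layer, exploiting the fact
that the BCM threshold theta tracks the square of the trained
response.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .core import heaviside
from .plasticity import BCMParams, OjaParams, bcm_update, oja_update

__all__ = [
    "StimulusPrototype", "HebbianLayer", "Vocabulary",
    "make_prototypes", "observe", "background",
    "make_layer", "recognize", "learn_label", "calibrate_theta_h",
    "register_pattern", "prototypes_to_json", "prototypes_from_json",
]

# floor below readout thresholds so an untrained (all-zero) layer never
# "recognizes" everything through the >= boundary convention
_THRESH_FLOOR = 1e-9


@dataclass(frozen=True)
class StimulusPrototype:
    """One stimulus class: registry index, name, prototype feature
    vector mu (non-negative, unit norm) and observation noise scale."""

    index: int
    name: str
    mu: np.ndarray
    sigma_noise: float = 0.0


@dataclass
class HebbianLayer:
    """Supervised Hebbian classification layer ``v = H u``.

    ``rule`` selects Oja or BCM updates; ``theta`` holds the per-class
    BCM sliding thresholds; ``theta_H`` is the fixed Oja readout
    threshold (+inf until calibrated, i.e. nothing is recognized);
    ``c`` scales the BCM readout threshold ``c * sqrt(theta_i)``.
    """

    H: np.ndarray
    rule: str
    params: object
    theta: np.ndarray
    theta_H: float = np.inf
    c: float = 0.5


@dataclass
class Vocabulary:
    """Ordered registry of stimulus names; registration fills the first
    empty slot, up to capacity K."""

    capacity: int
    names: list = field(default_factory=list)


def make_prototypes(K: int, ell: int, sigma_noise: float,
                    seed: int) -> list[StimulusPrototype]:
    """Deterministically generate K orthogonal non-negative unit-norm
    prototypes of dimension ``ell``.

    Each class occupies a disjoint block of ``ell // K`` feature
    dimensions with |N(0,1)| entries, normalized.  Orthogonality gives
    pairwise Euclidean distance sqrt(2), which must exceed the
    4*sigma_noise separation requirement.
    """
    if K < 1 or ell < 2:
        raise ValueError("need K >= 1 and ell >= 2")
    if ell // K < 1:
        raise ValueError(f"feature dimension {ell} too small for {K} classes")
    if sigma_noise < 0:
        raise ValueError("sigma_noise must be >= 0")
    if np.sqrt(2.0) <= 4.0 * sigma_noise:
        raise ValueError(
            f"separation infeasible: prototype distance sqrt(2) <= "
            f"4*sigma_noise = {4 * sigma_noise}")
    rng = np.random.default_rng(seed)
    block = ell // K
    names = [chr(ord("A") + i) if i < 26 else f"S{i}" for i in range(K)]
    protos = []
    for i in range(K):
        mu = np.zeros(ell)
        seg = np.abs(rng.standard_normal(block))
        mu[i * block:(i + 1) * block] = seg / np.linalg.norm(seg)
        protos.append(StimulusPrototype(index=i, name=names[i], mu=mu,
                                        sigma_noise=sigma_noise))
    return protos


def observe(proto: StimulusPrototype | None, rng: np.random.Generator,
            ell: int | None = None, sigma_noise: float | None = None):
    """Draw one observed feature frame.

    With a stimulus shown: ``max(0, mu + sigma*noise)`` elementwise.
    With none shown: a low-magnitude background vector (noise only);
    ``ell`` and ``sigma_noise`` must then be supplied.
    """
    if proto is not None:
        frame = proto.mu + proto.sigma_noise * rng.standard_normal(len(proto.mu))
    else:
        if ell is None or sigma_noise is None:
            raise ValueError("background frames need ell and sigma_noise")
        frame = sigma_noise * rng.standard_normal(ell)
    return np.maximum(frame, 0.0)


def background(ell: int, sigma_noise: float, rng: np.random.Generator):
    """Convenience wrapper: the no-stimulus frame."""
    return observe(None, rng, ell=ell, sigma_noise=sigma_noise)


def make_layer(K: int, ell: int, rule: str = "bcm", params=None,
               theta_H: float = np.inf, c: float = 0.5) -> HebbianLayer:
    """Zero-initialized classification layer (all Hebbian matrices start
    at zero)."""
    if rule not in ("oja", "bcm"):
        raise ValueError("rule must be 'oja' or 'bcm'")
    if params is None:
        params = OjaParams() if rule == "oja" else BCMParams()
    theta0 = params.theta0 if isinstance(params, BCMParams) else 0.0
    return HebbianLayer(H=np.zeros((K, ell)), rule=rule, params=params,
                        theta=np.full(K, float(theta0)), theta_H=theta_H, c=c)


def recognize(layer: HebbianLayer, u) -> np.ndarray:
    """Binary recognition vector for frame ``u``.

    Raw responses ``H u`` pass a Heaviside step: against the fixed
    ``theta_H`` for Oja, against the per-class sliding scale
    ``c * sqrt(theta_i)`` for BCM.  Output entries are in {0, 1} and
    feed the ring's input drive.
    """
    u_arr = np.asarray(u, dtype=float)
    if u_arr.shape != (layer.H.shape[1],):
        raise ValueError(f"frame must have length {layer.H.shape[1]}")
    raw = layer.H @ u_arr
    if layer.rule == "oja":
        if not np.isfinite(layer.theta_H):
            return np.zeros_like(raw)
        thresh = max(layer.theta_H, _THRESH_FLOOR)
        return np.asarray(heaviside(raw, thresh), float)
    thresh = np.maximum(layer.c * np.sqrt(np.maximum(layer.theta, 0.0)),
                        _THRESH_FLOOR)
    return (raw >= thresh).astype(float)


def learn_label(layer: HebbianLayer, u, label_index: int,
                dt: float = 1.0) -> HebbianLayer:
    """One supervised training step: clamp the labeled entry of v to 1
    and update that row of H (and, for BCM, its sliding threshold) with
    the layer's rule.

    Supervision gates plasticity to the named unit only.  Updating the
    unlabeled rows from their self-generated responses lets every
    labeling event of any class drag every sliding threshold toward the
    (near-zero) instantaneous cross-response, which collapses the BCM
    readout margin and floods the network with spurious recognitions;
    gating to the labeled row keeps each theta_i anchored at the
    trained response of its own class.
    """
    K, ell = layer.H.shape
    if not 0 <= label_index < K:
        raise ValueError(f"label index {label_index} not registered (K={K})")
    u_arr = np.asarray(u, dtype=float)
    if u_arr.shape != (ell,):
        raise ValueError(f"frame must have length {ell}")
    H_new = layer.H.copy()
    theta_new = layer.theta.copy()
    k = label_index
    if layer.rule == "oja":
        H_new[k] = oja_update(layer.H[k], 1.0, u_arr, layer.params, dt)
    else:
        H_new[k], theta_new[k] = bcm_update(
            layer.H[k], float(layer.theta[k]), 1.0, u_arr, layer.params, dt)
    return HebbianLayer(H=H_new, rule=layer.rule, params=layer.params,
                        theta=theta_new, theta_H=layer.theta_H, c=layer.c)


def calibrate_theta_h(layer: HebbianLayer, protos, factor: float = 0.5) -> HebbianLayer:
    """Set the Oja readout threshold to ``factor`` times the weakest
    trained prototype response.

    Called once after the naming stage; until then theta_H is +inf and
    the Oja readout recognizes nothing.
    """
    if layer.rule != "oja":
        return layer
    responses = [float(layer.H[p.index] @ p.mu) for p in protos]
    theta_H = factor * min(responses)
    return HebbianLayer(H=layer.H.copy(), rule=layer.rule, params=layer.params,
                        theta=layer.theta.copy(), theta_H=theta_H, c=layer.c)


def register_pattern(vocab: Vocabulary, name: str) -> int:
    """Return the index of ``name``, registering it in the first free
    slot if new.  Idempotent; raises when capacity is exhausted."""
    if name in vocab.names:
        return vocab.names.index(name)
    if len(vocab.names) >= vocab.capacity:
        raise ValueError(f"vocabulary capacity {vocab.capacity} exhausted")
    vocab.names.append(name)
    return len(vocab.names) - 1


def prototypes_to_json(protos) -> str:
    return json.dumps([
        {"index": p.index, "name": p.name, "mu": p.mu.tolist(),
         "sigma_noise": p.sigma_noise}
        for p in protos])


def prototypes_from_json(text: str) -> list[StimulusPrototype]:
    return [StimulusPrototype(index=d["index"], name=d["name"],
                              mu=np.asarray(d["mu"], float),
                              sigma_noise=d["sigma_noise"])
            for d in json.loads(text)]
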