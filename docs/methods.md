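# Methods

## Neuron and time model

All units are linear firing-rate neurons, `v = f(w·u)`, advanced on a
discrete clock; one step represents `dt` seconds of protocol time
(default 1 s). Continuous-time rules are integrated by forward Euler
with this global `dt` — the reduced STDP rule is itself a one-step
discretization, so a higher-order integrator would add cost without
adding fidelity. Activities are non-negative; the clipped activation

    σ_l(x) = 0 for x < l,  x for l ≤ x ≤ 1,  1 for x > 1

maps net input onto [0, 1] with a silence threshold `l = 0.1`
everywhere. Weights are stored raw (unclipped) and read through
`κ(W) = clip(W, 0, 1)`, so learning can accumulate past saturation
while the dynamics only ever see weights in [0, 1]. Heaviside readouts
treat the boundary `x = θ_H` as recognized, keeping recognition sets
closed. Dense float64 arrays throughout; equality tolerance in tests is
1e-9 unless a test states otherwise.

## Plasticity rules

**Oja** `τ_w dw/dt = v·u − β v² w` (defaults `τ_w = 1`, `β = 1`; the
effective learning rate is `dt/τ_w`, and no numeric `τ_w` is mandated
by the underlying model, so rate is controlled through `dt`). The
quadratic decay bounds ‖w‖, and with self-generated `v = w·u` on
stationary input `w` converges to the unit-norm leading eigenvector of
the input second-moment matrix — verified in the tests against
`numpy.linalg.eigh` of the empirical second-moment matrix, with a
Robbins–Monro decaying step over a frozen sample set (a constant step
would leave O(dt) stochastic jitter around the eigenvector).

**BCM** `τ_w dw/dt = v·u·(v − θ)`, `τ_θ dθ/dt = v² − θ` (defaults
`τ_w = τ_θ = 1`, `θ₀ = 0`). Both updates are synchronous (use
pre-update values): the update order is otherwise ambiguous and the
synchronous choice is the reproducible one. The threshold relaxes to
`v²` along `θ(t) = v² + (θ₀ − v²)e^(−t/τ_θ)`, which the tests check
per-step against the Euler track.

**Reduced STDP** `Δw = (dt/τ_w)(h₁ v(t)u(t−1) + h₂ v(t−1)u(t))`,
`h ∈ {−1,0,1}²`. `h=(1,−1)` is the antisymmetric LTP/LTD pair;
`h=(1,0)` is LTP-only. The continuous window is implemented as
`H(τ) = sign(τ)·a/max(|τ|, ε)` with `a = 1/40`, zero beyond the 50 ms
physiological cutoff and at τ = 0; `ε` regularizes the divergence at
the origin and defaults to the sampling spacing. A printed form of the
window without the reciprocal is inconsistent with both the decaying
shape of the empirical curve and the `1/τ_k` factors of the
discretization that yields the reduced rule, so the reciprocal form is
used. The quadrature of the window integral over two-pulse protocols
(pulses carry geometric `λ` decay tails, matching how the ring
prolongs activity) serves as an independent oracle: its sign agrees
with the reduced rule at every pulse separation in (0, 50 ms], both
orderings.

## The Ring

K neurons, full connectivity `S`, fixed diagonal `S_ii = λ = 0.8`
(chosen so that `λ^τ` stays above `l` for the 2–3-step delays the
protocol uses; the succession-convergence bound `⌈τ_w/(dt·λ^T₂)⌉`
degenerates when `λ^T₂` approaches numerical noise), dynamics
`r(t+1) = σ_l(κ(S)r(t) + f(v(t)))`, STDP on all off-diagonal entries
with post = row, pre = column. An isolated active neuron decays as
`λ^τ` until it falls below `l`, then is exactly 0 — this prolongation
is what lets a successor arriving T₂ steps later still find a
pre-synaptic trace of size ≥ `λ^T₂` to correlate with.

`present_pair` (the succession-learning demo operation) applies
learning through the step at which the successor fires and then lets
the ring settle to quiescence *without* learning. Learning through the
decay tail lets a saturated pair of reciprocal weights sustain each
other's activity indefinitely, after which weights grow without bound
and the exact LTP/LTD cancellation of balanced forward/reverse
pairings is destroyed; treating the pairing as the discrete learning
event preserves both the per-pairing increment bound and the exact
balance. The protocol runner, by contrast, keeps learning on at every
non-probe step: there the antisymmetric polarity (below) prevents the
runaway.

**Ring polarity default `h = (1, −1)`.** With LTP-only ring learning,
the overlap of A's decaying trace with B's sustained presentation also
potentiates the *reverse* weight B→A; once both directions saturate,
the pair becomes a self-sustaining attractor that never extinguishes
between trials and cross-links unrelated stimuli, collapsing every
probe contrast. The LTD term keeps reverse weights at or below zero,
so learned successions are one-way and activity always dies out in the
>30 s inter-trial gaps. Model A's reward link keeps the LTP-only
polarity `(1,0)`: its inability to unlearn is the very property the
A/B model contrast is about.

## Temporal-difference circuit

Per stimulus, a delay chain of `T = 10` slots (covers the 7 s maximum
reward delay at 1 step/s) whose first slot mirrors the ring neuron;
collector `y(t) = Σ w_j Δx_j(t)`; dopamine `z = reward + y`, not
clipped — extinction requires negative prediction errors; TD update
`w_j += α x_j(t−1) z(t)` with `α = 0.2` (a moderate default; the
underlying description leaves the rate open and only notes that larger
rates speed conditioning). Reward is a one-step unit pulse.

For an isolated circuit driven by a one-step stimulus pulse, rewarded
trials at delay d converge to the classical fixed point — z = 1 at
stimulus onset, z = 0 at reward time — and reward omission drives
z(onset) below any ε (same update, opposite sign). In the assembled
model the ring's decaying trace smears the stimulus representation, so
the converged onset response sits slightly below the isolated-circuit
value for single rewards (≈0.93 rather than 1.00 after 200 trials) and
above it when each trial carries several reward pulses: with the
protocol's three pulses (1, 4, 7 s), the onset response converges to
≈3 — onset dopamine comes to predict the *total* expected reward — and
crosses 1 within three trials.

## Synthetic perception

Each stimulus class is a non-negative unit-norm prototype occupying a
disjoint block of the `ℓ = 64` feature dimensions (dense random
non-negative vectors have expected cosine ≈ 2/π, which defeats any
fixed readout threshold; orthogonal prototypes emulate the highly
selective object-specific features the architecture presumes).
Observations add Gaussian noise (σ = 0.05 by default) clipped at zero;
prototype separation must exceed 4σ, checked at construction. A
no-stimulus frame is pure clipped noise. What this generator does
*not* emulate: correlated features across classes, occlusion, lighting
drift, or recognition errors under distribution shift — passing tests
show the architecture's learning dynamics are correct, not that a real
ConvNet front end would feed it clean enough recognitions.

The readout layer `v = Hu` starts at zero and learns only at labeling
events (one supervised step per naming utterance; recognition itself
is pure). Supervision clamps the labeled entry to 1 and updates *only
the labeled row* (and, for BCM, its threshold). Updating unlabeled
rows from their self-generated responses — the other resolution of
this genuinely open design point — lets every labeling event of any
class drag every sliding threshold toward the near-zero instantaneous
cross-response; the readout threshold then falls into the noise floor,
spurious recognitions saturate the ring, and the TD difference signal
vanishes entirely. Gating plasticity to the named unit anchors each
`θ_i` at the trained response of its own class.

Readout thresholds: BCM recognizes when the raw response reaches
`c·√θ_i` with `c = 0.5` — `θ` tracks `v²`, so `√θ` is the scale of the
trained response and the threshold slides with it (the "implicit
margin"). The Oja layer has no such scale, so its fixed `θ_H` is
calibrated once, after the naming stage, to half the weakest trained
prototype response; until calibration the Oja readout recognizes
nothing (which also keeps the zero-initialized layer from recognizing
everything through the ≥-boundary convention). Both thresholds carry a
tiny positive floor for the same zero-response reason.

## Protocol

Four stages, times in seconds at 1 step/s: naming (each stimulus shown
10 s with a labeling event at onset; 1 rep for Model A — multiple Oja
steps make a single fixed threshold increasingly awkward — and 5 for
Model B), preconditioning (A then B back-to-back with no gap between
members, likewise C then D; 6 trials of each pair), conditioning (B
shown 10 s with unit reward pulses 1, 4 and 7 s after onset, 9 trials;
D shown unrewarded), probes (each stimulus 3×, unrewarded, all
learning frozen so measurement cannot contaminate the learned state).
Inter-trial gaps are fixed at 31 s — above the mandated 30 s minimum
and deterministic, which matters because a gap must outlast both the
ring trace (11 steps) and the chain depth (10 steps) or the previous
trial's content contaminates the next trial's onset. Event generation
is a pure function of the configuration; the only randomness is the
seeded observation-noise stream, so runs are bit-reproducible from
(config, seed).

Summary statistic: peak z inside each probe window per stimulus, and
the contrasts `z(A) − z(C)`, `z(B) − z(D)`.

## Problem sizes

The shipped defaults are deliberately small — K = 4 stimuli, ℓ = 64
features, 2-neuron rings for the succession demos, ≤ 200-trial TD
runs, full-protocol horizons of ~2000–2700 steps — sizes at which every
reported behavior is exercised end-to-end in seconds on one core.

## Known limitations

- Extinction of a *multi-pulse* reward schedule is slow: after
  conditioning with three reward pulses per trial, the interaction of
  the sawtooth weight profile with the ring's decaying trace leaves a
  slowly decaying oscillatory residue, and some 30 unrewarded trials
  are needed before the peak probe response falls below 0.1 (single-
  pulse conditioning extinguishes below 0.1 within 20). The residue
  does vanish — the unrewarded trial map has the zero-weight state as
  its attractor — but the approach is not fast.
- Succession memory is Markovian: the ring encodes one-step
  successor relations, not longer sequences or context.
- The ring treats recognition as binary and noiseless once the
  readout margin is set; systematic misrecognition would write wrong
  successions into S, and nothing in the architecture repairs them.
- Self-decay λ is shared by all neurons; heterogeneous per-neuron
  decay is not modeled.
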