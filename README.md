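# ringsim

A desk-scale simulator of Hebbian/temporal-difference "ring" cognitive
architectures, built to replicate a classic sensory-preconditioning
experiment entirely in silico.

In the animal experiment, neutral stimuli are first paired (A then B,
C then D), one member of one pair is then conditioned (B followed by
reward, D not), and unrewarded probe trials finally show that dopamine
neurons respond to A — a stimulus that was *never* rewarded — more than
to C. The inference is transitive: A precedes B, B predicts reward,
therefore A predicts reward.

`ringsim` provides the pieces needed to reproduce that behavior with
rate-based neurons, and two end-to-end assemblies:

- **plasticity rules** — the Oja rule
  `τ_w dw/dt = v·u − β v² w`, the BCM rule with sliding threshold
  `τ_w dw/dt = v·u·(v − θ)`, `τ_θ dθ/dt = v² − θ`, and a reduced
  spike-timing rule `τ_w dw/dt = h₁ v(t)u(t−1) + h₂ v(t−1)u(t)` with
  polarity pair `h ∈ {−1,0,1}²`, plus the continuous STDP window
  `H(τ) = sign(τ)·a/|τ|` (zero beyond 50 ms) with a quadrature oracle
  for cross-checking the reduced rule;
- **the Ring** — a K-neuron recurrent network
  `r(t+1) = σ_l(κ(S)·r(t) + f(v(t)))` with fixed self-decay
  `S_ii = λ ∈ [0,1)` and STDP-learned cross-weights that come to encode
  temporal succession: each A-then-B pairing grows `S[B,A]` by at least
  `(dt/τ_w)·λ^T₂`, so after at most `⌈τ_w/(dt·λ^T₂)⌉` pairings,
  presenting A alone ignites B one step later;
- **a temporal-difference reward circuit** — per-stimulus delay chains
  `x_{i,1} = r_i`, a collector neuron
  `y(t) = Σ w_j (x_j(t) − x_j(t−1))`, a dopaminergic unit
  `z(t) = r(t) + y(t)` and the TD update
  `w_j ← w_j + α x_j(t−1) z(t)`;
- **a synthetic perception front end** — orthogonal non-negative
  prototype feature vectors with additive noise standing in for a
  ConvNet, and a name-supervised Hebbian readout layer `v = Hu`;
- **Ring Model A** (Oja readout + a single STDP reward neuron, which can
  learn but never unlearn a reward association) and **Ring Model B**
  (BCM readout + TD circuit, which also extinguishes associations when
  reward stops).

## Worked example

Succession learning on a two-neuron ring (λ = 0.8, l = 0.1, delay two
steps, LTP-only polarity):

```
$ ringsim demo-proposition1 --h 1,0 --presentations 2
raw S[B,A] after 2 presentations: 2.4000
r_B one step after presenting A alone: 1.0000
```

Two pairings suffice because each adds at least λ² = 0.64 (here 0.8 at
the pairing plus further correlation during the decaying traces), the
raw weight passes 1, and the read-time clip κ saturates the effective
weight, so driving A propagates a full-strength activation to B.

The full four-stage protocol (naming, preconditioning, conditioning,
probes) on Ring Model B:

```
$ cat cfg.yaml
sigma_noise: 0.0
conditioning_reps: 9
probe_reps: 1
$ ringsim run --model B --config cfg.yaml --seed 1 --out traces.csv --summary summary.json
wrote 30563 trace records to traces.csv
peak_z_A: 1.9749
peak_z_B: 1.8994
peak_z_C: 0.0000
peak_z_D: 0.0000
contrast_AC: 1.9749
contrast_BD: 1.8994
```

`peak_z_X` is the largest dopaminergic activity inside an unrewarded,
learning-frozen probe of stimulus X. B was conditioned, so probing it
elicits a strong onset response (the three reward pulses per trial push
the prediction above 1); A elicits nearly the same response purely
through the learned A→B succession in the ring — the transitive
inference — while C and D stay silent. The positive contrasts
`z(A) − z(C)` and `z(B) − z(D)` are the experiment's headline result,
and `ringsim run --model A` shows the same pattern (with peaks clipped
at 1 by Model A's saturating reward neuron).

Traces are long-format CSV (`t,signal,value`) with per-step recognition
(`v_*`), ring (`r_*`), BCM-threshold (`theta_*`) and dopamine (`z`)
signals, convenient for `pandas.pivot`.

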