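# Methods

This note documents the models implemented in `snnclust`, the choices made
where the design was genuinely open, the regime the default parameters put
the network in, and the known limits of what the synthetic experiments
show.

## Neuron and synapse models

Two backends implement the same functional network.

**Map backend** (`backend="map"`, Δt = 0.5 ms). Neurons follow a
discrete-time map with a fast voltage variable and a slow adaptation
variable `m ∈ [0,1]`:

```
V(t+Δt) = V_spike²·α / (V_spike(1+y) − V(t) + β·I_syn·(1−m))   if V(t) ≤ 0
V(t+Δt) = V_spike(α+y)    if 0 < V(t) ≤ V_spike(α+y) and V(t−Δt) ≤ 0   (spike)
V(t+Δt) = −V_spike        otherwise
m(t+Δt) = (1 − a·Δt)·m;   on spike m ← m + b(1−m)
```

with V_spike = 60 mV, α = 3, y = −2.468, β = 0.0165 mV/nA, a = 10⁻⁴/ms,
b = 0.02. The spike peak is V_spike(α+y) = 31.92 mV and the trough
−60 mV: amplitude 91.92 mV. Synaptic current is depolarizing-positive
throughout this package, so the per-afferent contribution is
`−g·S(V−V_syn)` and the update uses `+β·I_syn(1−m)`; this composes to the
same dynamics as feeding the raw conductance current into the textbook
form with `−β`, and keeps "excitatory input excites" true in both
backends. Left to itself the map has no resting fixed point: it orbits a
three-step cycle (−60 → −384.6 → +36.4 → −60) without ever entering the
spike branch; depolarizing input deepens the plunge so the rebound lands
in the spike window. We characterize this empirically rather than assume
rest. Conductance synapses carry an activation `S` per presynaptic neuron
(`S ← S+1` on a spike, geometric decay with τ_syn otherwise); τ_syn is
nowhere stated for this model and defaults to 2 ms excitatory / 10 ms
inhibitory. Reversal potentials are 0 mV (excitatory) and −92 mV
(inhibitory).

**LIF backend** (`backend="lif"`, Δt = 1 ms). Euler-integrated leaky
integrate-and-fire, τ_m = 20 ms, rest −66 mV, threshold −65 mV
(inclusive), reset −70 mV, 2 ms refractory; exponential current synapses
(`I ← I(1−Δt/τ) + Σ g_syn` per arriving spike). Only the product `I·R`
enters the membrane equation, so the input resistance `R` is the free gain
of this backend; see "Operating regime" below. Synaptic transmission has a
one-timestep delay; Poisson sources are Bernoulli approximations
`p = rate·Δt`.

## STDP

The four-branch window (constants above, in the README) is evaluated
**per spike pair**: every (pre, post) pair with ΔT ∈ (−200, 200] ms
contributes once. The alternative nearest-neighbour policy
(`STDPRule(pairing="nearest")`) pairs each spike with the most recent
opposite spike only. All-pairs is the default because the qualitative
mechanism the network depends on — uncorrelated or slow responders are net
depressed, only tightly causal responses potentiate — holds only when the
wide depression branches accumulate per pair: at 40 Hz uncorrelated
pre/post firing the expected drift is ≈ −0.04 µS per post spike under
all-pairs but ≈ +0.045 µS under nearest-neighbour (the narrow linear
branch dominates a single pairing).

Implementation: the summed window value over a presynaptic spike history
is a linear function of three per-band spike counts plus the middle-band
age sum, all maintained incrementally as spikes age (O(neurons) per step,
no pair scans); a brute-force pair enumeration cross-check is part of the
test suite. Pairing buffers are cleared at every presentation onset so no
pairing spans two input patterns. An integral property of the window worth
knowing: for a response at time T after stimulus onset, the net Δg over a
40 Hz afferent changes sign at T ≈ 156 ms (potentiation integral
1.70 µS·ms against 0.0125 µS/ms of depression — rate-independent). Faster
responses potentiate, slower responses depress; this is the selection
pressure that shapes the cluster layer.

## Operating regime (LIF defaults)

The paper-printed weights (initial U[g_max/2, g_max], inhibition
0.025/0.015, teaching 0.5) fix all ratios; the LIF gain `R` per layer is
the one free scale. The defaults are set by a rheobase rule:

* `r_cn = 0.15 mV/nA` puts the mean synaptic drive of a *naive* cluster
  neuron under the default stimulus (≈59 active pixels × 10 input neurons
  × 0.75 connectivity at 40 Hz through mean weight 0.1875, τ_exc = 2 ms)
  just above rheobase (threshold−rest = 1 mV). Naive first-spike latencies
  are then ~50–100 ms and fluctuation/heterogeneity-dominated, while a
  potentiated specialist (+33% on its template pixels) responds
  deterministically in ~20–25 ms. Presentations end at the CN spike limit,
  so familiar inputs are skipped quickly and novel ones dwell — the
  novelty mechanism. Far above this point every neuron fires within a few
  milliseconds of any stimulus and no competition or novelty signal
  exists; far below, all responses land beyond the 156 ms crossover and
  the weights erode monotonically (measured: a 6-pass probe at 6% lower
  gain diverged, durations 223→1588 ms).
* `r_an = 30 mV/nA` makes a cluster-layer burst through naive readout
  weights cross the AN rheobase while the teaching drive (1.2 nA) is
  strongly suprathreshold.
* `tau_inh = 30 ms` (CN): lateral inhibition must integrate across the
  response-latency gap to bias the race. `tau_inh_an = 15 ms` (AN): the
  readout competition must decay between 100 ms decision windows — with
  the CN value the previous winner's inhibitory tail outlives the silence
  and the readout locks its decision across presentations.
* The inhibitory teaching route uses the fast τ (2 ms): teaching switches
  per presentation, and a slow inhibitory tail suppresses the next
  presentation's target group. Teaching is likewise gated off during the
  50 ms silences; a teaching tail keeps the readout firing 20–200 ms after
  the CN burst, where the window depresses, and undoes the association.
* Plasticity is frozen during the test stage by default
  (`plasticity_during_test`, switchable). With binary flip noise, the
  noise pixels of every test presentation fire at the full rate and
  potentiate, converting specialists into generalists over a long
  stratified test run (measured ≈3× accuracy loss when left on).

## Synthetic data

The generator emulates the relevant structure of a digit benchmark at
desk scale: `n_classes` fixed binary prototype templates on a 16×16 grid
(28×28 for MNIST-parity runs), samples = template + independent per-pixel
flip noise (default 5%; the expected sample-to-template Manhattan distance
is `q·d`). Templates are equal-area, mutually disjoint blobs drafted
round-robin from noise-perturbed distance fields around ring anchors:

* *equal area* because the rate-coded drive scales with stimulus ink, and
  the near-rheobase regime cannot tolerate systematic per-class drive
  differences;
* *disjoint* because overlapping prototypes hand neurons tuned to one
  class a drive head start on the overlapping class that exceeds the ~3%
  static selectivity margin; at small cluster counts the first classes
  presented then capture the entire layer;
* *near-full coverage* (union ≈ 255/256 pixels) so that the pixels no
  class ever stimulates — which keep their high initial weights, as no
  spike pairing ever touches them — fall inside the 10% least-active-pixel
  mask used by every feature-space comparison.

What the generator does **not** emulate: graded pixel intensities
(anti-aliased stroke edges), within-class shape variation, unequal class
ink budgets, and correlated noise. In particular the binary flip noise is
maximally corrosive for always-on plasticity (see above); conclusions
about the always-learning regime do not transfer from these experiments to
graded data.

## Evaluation choices

Pseudo-patterns average the weights of the synapses that actually exist
(a strict full-fan-in mode is available), are scaled by 255/g_max and
rescaled to [0,1] before any distance. The active-pixel mask drops the
`floor(0.1·d)` least-active pixels of the training set, ties broken by
pixel index; the same mask is applied to the network's centers and to the
k-means / neural-gas baselines for fairness. Snapshots for the distance
trajectory are taken every ⌈N/8⌉ presentations of epoch 1. Ties in the
classification argmax go to the lowest group index and are flagged; a
window with zero readout spikes is scored as an (incorrect) no-decision.
Neural gas uses two shuffled passes, λ: 10→0.5 and ε: 0.5→0.05 with
exponential schedules. k-means and PCA come from scikit-learn.

## What the default experiment does and does not reach

At the default desk scale (5 classes, K = 10 cluster groups × 30 neurons,
0.4·K = 4 training digits per class, two epochs, spike limit 20) the
simulator reproduces the qualitative signatures of the method: presentation
durations fall as inputs become familiar, per-neuron class specificity of
the cluster code approaches 1.0 during training, and held-out
classification reaches 67–83% across seeds (chance 20%). It does **not**
reach three quantitative marks at this scale, for structural reasons
documented with measurements in the test suite and analysed above: (i)
single-group WTA dominance — the inhibitory fan-in scales with K, and at
K = 10 the pinned 0.025 inhibition shifts a rival's drive by ~1–3% of
threshold; (ii) group-averaged pseudo-patterns matching the templates —
with 8 exposures per class, class identity lives in a few specialist
neurons per group and the 30-neuron average stays near the initial gray;
(iii) a mean nearest-cluster distance within 1.5× of k-means — k-means
with 10 centers on 20 training points is near-degenerate. All three are
expected to relax toward the published full-scale behaviour as K, the
training budget (0.4·K per class) and with them the inhibitory fan-in
grow together.
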