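# Methods

## The model

`remapnet` simulates a four-population rate network that learns, without
supervision, to *remap* visual activity across saccades: to hand activity
to the neurons whose receptive field (RF) will contain a stimulus after an
impending eye movement. Space is one-dimensional. All trials begin fixating
straight ahead, so a stimulus at head-centered location `h` first appears
at retinal location `h`, and a saccade to retinotopic target `s` moves it
to `h − s`.

Populations (sizes in parentheses are the defaults):

- **Visual** (`N_V = 91`, integer preferences on [−45°, 45°]): an
  event-driven retinal map with a memory trace. The rate of neuron *i*
  jumps by `exp(−(α_i − Ψ)² / 2σ_V²)` at stimulus onset (Ψ is the current
  retinal stimulus location, σ_V = 3°), holds without leak through stimulus
  offset, and is cleared and re-evaluated at the post-saccadic stimulus
  location a fixed delay Δ_V = 280 ms after saccade onset. The long
  post-saccadic persistence stands in for conduction delays and attractor
  dynamics across visual areas; it is imposed, not emergent.
- **Saccade** (`N_S = 61` on [−30°, 30°]): leaky units
  (τ = 20 ms) driven by a Gaussian of the saccade target inside the window
  `[t_sacc − 70 ms, t_sacc + 300 ms]`, boundary-inclusive.
- **Combination** (`N_C = 1000`): leaky integrators of diluted excitatory
  input from both input populations (ψ_V→C = 10, ψ_S→C = 8; each neuron
  draws round(91·0.05) = 5 visual and round(61·0.20) = 12 saccade
  afferents), minus global lateral inhibition (0.1 × Σ rates, self
  included), passed through a steep sigmoid (slope 100, threshold 15).
  The threshold sits above what either input alone can deliver, so these
  neurons fire only when a planned saccade coincides with a remembered
  stimulus — they are conjunction detectors for (pre-saccadic stimulus
  location, saccade target).
- **Remapping** (`N_R = 91` on [−45°, 45°]): leaky integrators of weighted
  combination input (ψ_C→R = 3), lateral inhibition (0.6 × Σ rates), and a
  direct visual drive `K` with tonic trace `P`. `K` relaxes (τ = 20 ms)
  toward ψ_K × Gaussian of the stimulus while the stimulus is visible
  (gated per neuron by an onset delay Γ_i ~ |N(0, 50 ms)| clipped at
  80 ms); at stimulus offset `P` jumps by the current `K` and then decays
  with τ_P = 300 ms while feeding `K`, producing the trace response; both
  are zeroed Δ_K = 0 ms after saccade onset (response truncation). The rate
  sigmoid has slope 0.5 and threshold 3.

A note on `N_R`: the default is 91 — one neuron per integer retinal
location, matching the visual population, and the variant all analyses
here use. A much larger remapping population (say 5000) makes the global
inhibition term `0.6 × Σ v_R` ~55× stronger, which pushes the network into
a sparse, strongly suppressed regime where single-neuron responses of
order 0.5 are unattainable. Larger populations are nevertheless supported
and assign preferences cyclically over the 91 integer locations.

## Learning

The three projections (visual→combination, saccade→combination,
combination→remapping) are plastic: `dW_ij/dt = ρ · post_i · pre_j` with
ρ = 0.1 per second, followed by rescaling each postsynaptic weight row to
unit L2 norm after every update. Renormalization makes the rule
competitive: a row is an exponential moving average of the pre-patterns it
was paired with, with a forgetting rate set by the per-step increment.

The time unit of ρ matters and is a deliberate design choice. With the
integration grid in milliseconds, reading ρ as "per ms" gives per-step
increments of ~0.2 on a unit-norm row, so renormalization erases all but
the last ~20 ms of training — the learned efferent structure then reflects
only the final steps of the final trial, which contradicts the intended
behavior (efferent weight mass proportional to co-activation time, and
input preferences only mildly reshaped by training). Per-second rates give
per-step increments of 2×10⁻⁴ and weight vectors that integrate pairings
over the whole training history. We therefore integrate the weight ODE
with dt in seconds. One consequence worth knowing: at 20 epochs the
post-training weight alignment is moderate (decoded combination-preference
correlations pre/post ≈ 0.98–1.00), and the weakest-recruited remapping
neurons can remain below the latency-decodability threshold (see
Limitations).

During training, learning is applied after each Euler step using the
current rates, only when at least one combination neuron is active (the
update is exactly zero otherwise), and each training trial starts from a
zeroed network state. No learning occurs during any test battery.

## Protocols

- **Training trial**: stimulus on for the whole trial, saccade at 200 ms,
  450 ms of post-saccadic fixation (≈700 ms total; snapped up to the
  integration grid). A training set is `M = 17` integer pairs `(h, s)`
  sampled uniformly (rejection sampling) under the constraints |s| ≥ 10°,
  `h − s` within [−45°, 45°]. The experiment drivers additionally require
  the 17 post-saccadic locations `h − s` to be distinct so that each trial
  has its own analysis neuron. Training runs 20 epochs with the trial
  order reshuffled (seeded) each epoch.
- **Stimulus control** (91 trials): 100 ms flash at each integer retinal
  location, no saccade, 900 ms.
- **Saccade control** (61 trials): saccade at 100 ms, no stimulus, 900 ms.
- **Probe** (61 × 91 = 5551 trials): stimulus on throughout, saccade at
  200 ms, 700 ms total (the training-trial template whose timing it
  shares).
- **Single step** (one per training pair): flash at `h_i` during
  100–200 ms, saccade `s_i` at 600 ms, 900 ms.
- **Delayed stimulus flash** (26 per pair): 50 ms flashes at 13 onsets
  (100–700 ms in 50 ms steps) around the 600 ms saccade, in two families —
  current-RF (head-centered `h_i − s_i`, the analysis neuron's
  pre-saccadic RF) and future-RF (head-centered `h_i`). Trials last
  1100 ms so that the latest stimulus-aligned analysis window
  (onset 700 + 50 + 300 ms) fits inside the trial; with shorter trials the
  zero-padded tail artificially depresses the late future-RF points, which
  should saturate. The 50 ms flash duration is a choice ("briefly
  flashed"); it is configurable.

Absent stimulus or saccade is an explicit sentinel (`None` in trial
specifications, `NaN` in sampled kinematics), never a large float, so
Gaussian drives evaluate to exactly zero.

## Numerical scheme

Forward Euler with `dt = min(τ)/10 = 2 ms` over the six neuronal time
constants. Per step: (1) continuous Euler updates of every state variable
using previous-sample rates (synchronous update — population order cannot
matter), (2) discrete event jumps, (3) sigmoid nonlinearities,
(4) plasticity. Dirac-δ terms are events with the stated jump magnitudes,
not scaled by τ or dt; an event between samples fires at the first sample
at or after its time. The stimulus is visible on `[t_on, t_off)`; the
perisaccadic and drive-gating windows are boundary-inclusive. State is
reset to zero between trials. Convergence is first order in dt (checked by
Richardson-style halving against a dt/8 reference); all reported analyses
use the 2 ms grid.

## Analysis

- **Period response**: trapezoidal time average over a closed window
  `[t₁, t₂]` on the sample grid. (The trapezoid needs both endpoints, so
  windows are closed rather than half-open; with 2 ms samples over 300 ms
  windows the distinction is one half-sample at each end.) Windows that
  outrun a trial can optionally be zero-padded (trial over ⇒ silence).
- **Response latency**: the start of the first 30 ms window in which the
  per-ms slope of the rate exceeds 0.002 at every sample step; neurons
  with no such window are unresponsive in that trial. Remapping latencies
  are reported saccade-aligned (minus 600 ms); visual-onset latencies
  stimulus-aligned (minus the flash onset).
- **Remapping index**: remapping activity is the period response over
  `[t_sacc, t_sacc + 300 ms]` of the single-step trial. The visual index
  subtracts the period response over [600, 900] ms of the stimulus-control
  trial at the pre-saccadic stimulus location; the saccade index subtracts
  the saccade-aligned 300 ms response of the matched saccade-control
  trial. The index is the Euclidean norm of the two, hence bounded by √2;
  the alternative 1-norm (bounded by 2) is not used and values are never
  rescaled. The fixed [600, 900] control window is used verbatim, with the
  50 ms onset-delay compensation regarded as already folded into it.
- **Classification**: predictive ⇔ remapping latency < visual-onset
  latency from the neuron's own-RF stimulus-control trial; pre-saccadic ⇔
  remapping latency < 0. An undecodable latency makes both false.
  Population latency means include only decodable neurons.
- **Probe decoding**: each combination neuron's preference is the center
  of mass of the initial retinal location (and, separately, the saccade
  target) over all 5551 probe trials, weighted by the neuron's period
  response over the 50 ms saccade-aligned window; neurons with total
  response below 10⁻⁶ are undecodable.
- **Responsiveness curves**: per delayed-flash family and onset time, mean
  and SD across the 17 analysis neurons of the period response over
  `[onset + 50 ms, onset + 350 ms]`.
- **Multidirection counts**: a neuron remaps a trained location if the
  single-step remapping index is positive and exceeds the index of the
  same trial on the matched untrained network.

## Experiments

1. **Predictive remapping**: build the default network, evaluate all 17
   analysis neurons untrained, train 20 epochs, re-evaluate; optionally
   decode combination preferences from the probe battery before and after
   training. Untrained baselines reuse the same connectivity and initial
   weights as the trained run.
2. **Responsiveness shift**: both delayed-flash families on the trained
   network of experiment 1 and on its untrained twin.
3. **Multiple directions**: four distinct training pairs per original
   post-saccadic location (68 trials), retrained from scratch for each
   value of the combination→remapping connectivity fraction φ_C; neurons
   scored 0–4 by the classification rule above.

Seeding: one master seed is split (via `numpy` seed sequences) into
independent streams for connectivity, initial weights, onset delays,
training-set sampling, and epoch shuffling, so every run is reproducible
from its manifest.

## Problem sizes and runtimes

The test suite and the acceptance script use the defaults above (17 pairs,
20 epochs, full 5551-trial probe battery) — these are the study
conditions, not reduced stand-ins. The φ_C sweep is run at three values
{0.1, 0.5, 1.0} in the tests (the full 0.1–1.0 sweep is available through
the driver and CLI); the sweep's qualitative claim — denser connectivity
remaps more locations — only needs its endpoints. Batteries integrate as
batched matrix products; training is sequential by necessity.

## What the protocol generator does and does not emulate

Stimuli are single points, noiseless, and stationary in head-centered
space; saccades have a constant 300°/s velocity and perfect accuracy; at
most one stimulus and one saccade occur per trial. The model is
deterministic given its seeds — there is no trial-to-trial response
variability, so passing tests say nothing about robustness to sensory or
motor noise, multi-stimulus scenes, head movement, or 2-D geometry.
Latency heterogeneity comes only from the Γ onset delays and network
state, not from conduction-delay mechanisms.

## Known limitations

- **Recruitment sensitivity.** Whether a combination neuron ever fires for
  a given (h, s) depends on its random afferents pushing the fixed-point
  drive over the sigmoid threshold (15); near that threshold the number of
  recruited neurons roughly doubles per unit of drive. Pairs with extreme
  saccades (|s| near 30°, where the saccade-population Gaussian is
  truncated by the grid edge) recruit fewest. Remapping strength per
  neuron tracks recruitment, so a few of the 17 analysis neurons typically
  have weak, sometimes latency-undecodable, remapping; the exact count
  varies with the seed.
- **Gating tail.** The combination threshold (15) exceeds what either
  input alone typically delivers, but at most connectivity seeds a few of
  the 1000 neurons draw two or three visual afferents clustered within a
  degree or two; at that location the visual drive alone crosses
  threshold, so one or two saccade-free stimulus-control trials activate
  them. Gating is a property of the typical neuron, not a hard guarantee.
- **Plateau wiggle in the future-RF curve.** At late onsets the curve
  saturates, but onset-600 windows include combination-driven remapping
  activity while onset-650 flashes can still land mid-saccade for large
  |s|, producing a non-monotonic wiggle of ~0.03 about the plateau.
- The inhibition terms are global and linear; there is no topography, no
  spiking, and no conduction delay mechanism — delays are phenomenological
  parameters throughout.
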