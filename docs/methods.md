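# Methods

This package synthesizes event-specific beehive audio in two stages — a
raw-waveform GAN followed by a Metropolis–Hastings (MH) selection stage
in acoustic feature space — and evaluates the result with the same
reference classifier and distributional diagnostics a hive-monitoring
study would use. This note records the model, the choices made where
the design was genuinely open, the scaled-down study conditions, and
the limitations we have measured.

## Problem setting

Queen status is audible: hives with and without a queen differ in the
harmonic structure and slow amplitude modulation of the colony sound,
with nearly all acoustic energy below 2 kHz. Recordings of the rare
queenless state are scarce, which starves classifiers trained to detect
it. The framework therefore (1) learns a generative model of 1-s hive
clips for one event class at a time, (2) filters the generator's output
pool toward the acoustic feature distribution of real recordings, and
(3) measures whether the refined clips are classified as their target
event and whether they narrow the distributional gap to real audio.

## Preprocessing

Recordings are converted to mono (channel mean), downsampled by
polyphase rational resampling, trimmed of leading/trailing silence,
band-pass filtered, and cut into non-overlapping 1-s segments.

* Silence gate: frame RMS (1024-sample frames, 512 hop) against a
  threshold of −40 dB relative to the file's **peak frame RMS**. Only
  leading/trailing silent runs are removed, so quiet passages inside
  bee activity survive. An all-silent file contributes nothing and is
  logged.
* Band-pass: 4th-order Butterworth, 20–2000 Hz at the full rate,
  applied forward–backward (zero phase, so temporal envelope features
  are not smeared by group delay). Note the measured passband droop:
  the zero-phase cascade keeps ≥ 99% of tone energy up to ~0.55× the
  upper edge, 92% at 0.7×, but only 77% at 0.8× — energy-preservation
  guarantees are therefore stated for ≤ 0.7× of the band edge.
* Segmentation: trailing partial windows are zero-padded when at least
  25% full, else dropped; the policy is applied per file after
  trimming. Padding value is zero.

Defaults reproduce the full-scale geometry (16 384 Hz, 16 384-sample
segments). `desk_preprocess_config()` is the CPU profile used by the
test harness: 1024 Hz, 20–480 Hz band, 1024-sample segments (see
*Desk scale* below).

## Synthetic fixtures

The fixture generator emulates the documented gross properties of hive
recordings so the entire pipeline is testable without any external
dataset: 10-s clips at 32 kHz in three classes. Bee classes are a
harmonic stack (fundamental 250 Hz for queen-present, 330 Hz for
queen-absent; 7 harmonics capped below 2 kHz, amplitude ratio 0.7 per
harmonic) under a slow AM envelope (4 Hz vs 9 Hz, depth 0.5) plus
band-limited noise at 10 dB SNR; the no-bee class is low-pass-shaped
noise with no line structure. Every clip is peak-normalized to 0.9 and
fully determined by (label, config, master seed, clip index) through
spawned RNG streams.

Real hives vary from clip to clip, and that variability is
load-bearing: the MH prior is fitted to real feature (transition)
covariance, which collapses to a point mass if every fixture clip is
acoustically identical. Each clip therefore draws per-clip jitter:
fundamental ±4%, harmonic decay ±0.05, SNR ±3 dB, AM rate ±20% —
magnitudes chosen as plausible natural variation. What the fixtures do
**not** emulate: environmental noise (wind, rain, machinery),
non-stationarity within a clip, microphone/channel effects, and the
broad within-class diversity of real colonies. Fixture classes are
consequently far more separable than real data (the reference
classifier reaches ~100% on held-out fixtures), so passing tests
demonstrate mechanism correctness and directional behavior, not
real-data performance.

## WaveGAN

The generator maps a 100-dim latent vector through a dense layer and a
stack of transposed 1-D convolutions (kernel 25, stride 4, ReLU, tanh
output bounded to [−1, 1]); the critic mirrors it with strided
convolutions, LeakyReLU(0.2), and phase shuffle (random circular time
shift in ±2 samples per batch item) after every layer but the last.
Training is WGAN-GP: the critic maximizes the Wasserstein surrogate
with a gradient penalty λ·E[(‖∇ₓD(x̂)‖₂ − 1)²], λ = 10, on per-clip
uniform interpolates; Adam with lr 1e−4 (desk 2e−4), β₁ = 0.5,
β₂ = 0.9; five critic steps per generator step. Checkpoints (weights +
a fixed batch of 64 generated clips) are stored every 1000 iterations;
the converged checkpoint is the one whose stored clips the reference
classifier assigns most often to the target class, earliest iteration
on ties.

The network runs on a compact reverse-mode automatic differentiation
engine written for this package (`autodiff.py`). Its vector–Jacobian
products are themselves built from differentiable ops, so the gradient
penalty — a function of an input gradient — can be backpropagated into
the critic's parameters (double backprop). Convolutions lower to
`im2col`/`col2im` adjoint pairs around BLAS matmuls; transposed
convolutions are computed directly as matmul + overlap-add fold, which
keeps operands small. The engine works in float32 by default (float64
context available; finite-difference comparisons run there). With
fixed seeds and a given dtype the whole training loop is
bit-reproducible.

## Desk scale

The full-scale protocol (16 384-sample clips, channel multiplier 64,
120 000 iterations, batch 64) is retained as the `paper` preset but is
far outside a CPU-only budget. The `desk` preset is the package's
scaled-down analogue, sized so that its 2000 iterations genuinely
converge rather than merely run: 1-s clips at 1024 Hz (1024 samples,
3 conv layers), channel multiplier 8, batch 8, n_critic 5, lr 2e−4,
checkpoints every 1000. At this rate each fixture class reduces to its
fundamental tone plus noise floor — a distribution the small GAN can
learn in 2000 iterations (residual feature offsets ≈ 2–3σ of the real
spread; the Wasserstein estimate decreases over training). Earlier
candidates at a 4096 Hz desk rate left the GAN knowing only the
fundamental after 2000 iterations (offsets ≈ 15σ), which starves the
refinement chain (see below). Problem sizes used throughout the test
harness: 200 one-second segments per class (20 ten-second fixture
clips), generation pools of 500 clips, refinement targets of 500
acceptances, five seeds.

## Feature space and prior

The chain state θ is a 22-dim summary of one segment: 16 log-spaced
band energies over the hive band (dB, floored at −80), frame-RMS mean
and std (amplitude variation), spectral-centroid mean and std,
zero-crossing rate, and the normalized autocorrelation peak at 2–50 ms
lags (short-term temporal structure). The map is deterministic,
config-swappable, shifts by +6.02 dB per amplitude doubling in the
energy coordinates, and is scale-invariant in the centroid
coordinates.

The target density p(·) is a diagonal Gaussian fitted by moments with
a 1e−6 variance floor. Because the density is described as modeling
*transition* probabilities of real features, the default fits it to
differences of randomly paired real feature vectors (`prior_on:
transitions`); fitting to raw feature states (`prior_on: features`) is
the alternative reading and is available as a switch. Only density
ratios enter the acceptance rule, so normalization never matters and
all arithmetic is done in log space (no underflow at d = 22).

The classifier feature is 20 MFCCs per segment (26-filter mel bank to
Nyquist, DCT-II, frame-level coefficients averaged over frames —
chosen over frame-wise features for determinism and because one
vector per 1-s segment is the documented granularity).

## Metropolis–Hastings refinement

Candidates v are drawn uniformly with replacement from the generated
pool, r_t uniformly from the real set. The proposal is

    θ_prop = (1 − β)(v − s_t) + β(v − r_t),   0 ≤ β ≤ 1,

accepted with probability α = min(1, p(θ_prop)/p(θ_t)) against a
uniform u; on acceptance the chain state becomes θ_prop, the current
synthetic state s becomes v, and v's features are folded into an
exponential moving average (weight 0.2 on the new sample; the first
acceptance initializes the accumulator). No feature-to-waveform
inversion exists in this design, so the **emitted audio is the
accepted candidate's waveform**; the EMA-smoothed feature vector is
recorded as metadata alongside each emitted clip. The proposal budget
defaults to 50× the requested output count; exhausting it emits a
partial set with a warning rather than failing silently.

Open design points resolved here:

* **θ₀ initialization.** Initializing at a transition built from two
  *real* features deadlocks the chain whenever the pool is imperfect:
  that state's prior density exceeds anything a pool-based proposal
  can reach (measured deficits of hundreds of nats), so every proposal
  is rejected. θ₀ is therefore a transition of the proposal's own kind
  — built from an initial (candidate, state, real) draw at the
  configured β — which starts the chain inside the reachable density
  range while leaving the accept/reject rule untouched.
* **Acceptance-rate expectations.** The rule has no Hastings
  correction for the (independence-style) proposal, so the chain
  concentrates at states of above-typical density; its long-run
  acceptance rate is well below 1/2 even when pool and real sets are
  identically distributed (≈ 0.15 at d = 22). This is a property of
  the algorithm, not a defect of the pool.
* **Implementation.** Proposal densities do not depend on the chain
  state between acceptances, so `refine()` evaluates them in
  vectorized blocks and reduces the sequential part to scalar
  compares; `mh_step()` is the reference single-step operation (the
  two consume random draws in different orders, so each is
  deterministic for a seed but their chains are not sample-identical).

### What refinement can and cannot do

Refinement is *selection*: it reweights the pool toward members whose
features look real. It therefore improves exactly those feature
coordinates in which the pool is heterogeneous, and it cannot repair a
bias shared by every pool member. Two measured regime behaviors follow:

* Small β (smoothness-dominated, e.g. 0.01): the chain prefers small
  feature jumps and concentrates near the generator's mode. If that
  mode is slightly off-target, the refined set can sit marginally
  *farther* from real pooled histograms than the raw pool — we observe
  a small systematic worsening of the pooled frequency histogram at
  desk scale. A small β being optimal presupposes a generator whose
  mode is already on target.
* Large β (realism-dominated, 0.5–0.9): strong selection pressure and
  consistent distributional improvement (all three divergence kinds in
  4 of 5 desk seeds), but acceptance decays as the chain climbs, so
  reaching large output counts can exhaust the proposal budget.

At desk scale the reference classifier saturates (it assigns ~100% of
both raw and refined clips to the target class, because the fixture
classes are far apart, leaving no headroom for refinement to show up
in classification counts), so the β-sweep's count-based optimum
degenerates to a tie broken by grid order. The end-to-end acceptance test applies the count rule as
specified and is expected to fail its divergence clause at this scale;
the mechanism is documented above and the per-seed numbers are
reproducible from the test harness.

## Reference classifier and metrics

Standardize 20 MFCCs (z-score on training statistics) → LDA to C−1 =
2 dimensions → linear-kernel SVM with C = 1.0 (the simplest faithful
reading of a "simple SVM"; both knobs configurable). Metrics are
one-vs-rest precision/recall/F1 per class with the zero-division → 0
convention, overall accuracy, the full confusion matrix, and macro
averages (reports sometimes quote minority-class and sometimes macro
figures, so both are emitted).

The augmentation experiment freezes a stratified 80/20 real test split
before any augmentation (asserted by hash), caps real minority samples
at the first step's count — the scarce-data baseline — and reaches
each later minority proportion (20% → 26% → 30% → 33.3%, the 40:20:40
imbalance design) by adding refined synthetic minority clips only.

## Distributional diagnostics

Frequency (magnitude-spectrum mass), amplitude (sample histogram over
[−1, 1]), and spectral-centroid (Hann-windowed 1024/512 frames;
all-zero frame → centroid 0) distributions over 50 bins, pooled over
segment sets; realism gaps are quantified by Jensen–Shannon divergence
in nats (symmetric, 0 iff equal, ≤ ln 2, defined for disjoint
supports). LDA-plane projections of real / generated / refined sets
come with per-set centroids and dispersions. The divergence
quantification and bin count are this package's choices; the upstream
comparison was visual.

## Numerical and degenerate-input choices

Variance floor 1e−6 in the prior; log-energy floor −80 dB; sqrt in the
gradient-penalty norm guarded by 1e−12; empty histograms compare with
divergence 0; all-silent recordings yield empty waveforms and are
skipped with a log line; ties in checkpoint selection and β-sweeps go
to the earliest candidate; β is validated to [0, 1] everywhere.

## Known limitations

* The emitted "refined" audio is a reweighted subset (with
  replacement) of the generator's pool; refinement never synthesizes
  new waveforms and cannot correct uniform generator bias.
* The desk-scale classifier is saturated, which blunts count-based
  comparisons between refinement settings (see above).
* The MH stage is not a calibrated posterior sampler (no proposal
  correction); it is used as a stochastic selection heuristic, as
  designed.
* Fixture realism is deliberately minimal; no claim about real-hive
  performance follows from these tests.
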