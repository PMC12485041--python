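# Methods

This note documents the models, the synthetic data generators, the benchmark
conditions and the numerical choices behind `fgl`, including where the design
was genuinely open and what the package's tests do and do not demonstrate.

## The future-guided objective

The student minimizes `α·L_task + (1−α)·τ²·KL(p_T^τ ‖ p_S^τ)` where
`p^τ = softmax(logits/τ)`. Design points:

* **KL direction** is teacher-first (mode-covering). With a frozen teacher the
  gradient of the KL term with respect to the student logits is
  `τ·(p_S^τ − p_T^τ)`, so the implementation trains on an analytic gradient;
  tests verify it against numerical differentiation of the scalar loss.
* **`τ²` scaling** keeps the soft-term gradient magnitude roughly independent
  of `τ` (verified: gradient norms within a factor 2 across τ ∈ {1, 4, 10}),
  so `α` has a stable meaning.
* **Task loss** is cross-entropy against the one-hot bin label in binned
  regression mode and against the binary event label in event mode. A
  mean-squared-error task (on the softmax expectation over class indices) is
  available but not the default.
* **Degenerate inputs**: KL reports `inf` on a support mismatch rather than
  silently smoothing; an optional epsilon floor (off by default) exists for
  robustness experiments. A class map (injective teacher→student index map)
  relocates teacher probability mass when label spaces differ; with matching
  spaces the identity is assumed and a mismatch without a map is a
  configuration error.
* **Teacher freezing**: teachers are wrapped in a read-only structure whose
  parameter arrays are marked immutable and whose SHA-256 checksum is recorded
  at freeze time; optimizers refuse frozen models, and the student-training
  loop asserts checksum constancy.

## Models

All forecasters are compact fully-connected tanh networks over the flattened
input window, written in numpy with analytic backpropagation and seeded
Glorot initialization, trained with minibatch Adam (default) or SGD. The
package's claims are comparative — distilled vs baseline students of the
*same* architecture — so a small, bit-reproducible encoder family is
preferable here to a heavyweight recurrent one; recurrent and convolutional
encoders are out of scope for this implementation.

Inputs are standardized per feature using training-set statistics stored on
the model (applied identically at test time). Event-mode models prepend a
fixed feature front-end with no trainable parameters: per-channel log power
in eight equal frequency bands of the window periodogram (`bandpower`; a
time-domain variant `logpower` over sub-windows also exists). Spectral power
features are the standard practice for seizure work, and a tanh network on
raw samples cannot reliably represent signal energy at these sizes.

## Mackey-Glass benchmark

The generator integrates `dx/dt = β·x(t−τ_d)/(1 + x(t−τ_d)^n) − γ·x(t)` with
fixed-step RK4; the delayed value is read from the stored trajectory with
linear interpolation, so `τ_d/dt` need not be an integer. History is the
constant `x0`; a divergence (non-finite value) raises with the failing step
index. Defaults: β = 0.2, γ = 0.1, n = 10, τ_d = 17, dt = 1, x0 = 1.2,
washout 500 — the standard chaotic regime. Correctness anchors: the fixed
point `x* = (β/γ − 1)^{1/n} = 1` is preserved to < 1e−9; the trajectory
agrees with an independent 100×-finer Euler integration over the first 100
time units; halving `dt` shrinks the inter-grid discrepancy.

**Windows.** A student window of length L = 24 ends at `x_t` with target
`x_{t+n}`; the teacher window ends at `x_{t+n−1}` and the teacher is trained
as a next-step forecaster — teacher and student predict the same target from
different temporal vantage points. Splits are chronological (80/20), the bin
range is fit on training targets only, and test-time excursions beyond the
training range clamp to the edge bins (chaotic test segments must not crash
evaluation). Encoding uses half-open intervals with the last bin closed;
argmax decoding breaks ties toward the lower index. An optional purge gap
removes training windows that overlap the test region.

**Benchmark conditions** (the package's choices): series of 3000
samples; horizons 2–15; B ∈ {25, 50}; identical teacher/student MLPs with 64
hidden units; Adam 1e−3, batch 64; teacher pretrained for 100 epochs (the
next-step task is intended to be near its ceiling — the premise of the method
is a low-uncertainty teacher), students 30 epochs; τ = 4; α ∈ {0, 0.5}; three
seeds per cell controlling initialization and batch order. **Errors are
reported in bin-index units** (squared distance between predicted and true
bin index of the argmax decode), which makes errors directly comparable
across bin resolutions of the same signal. Value-space MSE of the decoded
scalar is computed alongside.

Under these conditions the distilled students beat the baseline at both
resolutions (≈12% pooled improvement at 25 bins, ≈26% at 50 bins, ≈21%
pooled over the full grid at master seed 1; individual aggregates move by a
few points across master seeds at three replicates per cell), the α = 0.5
student retains a modest edge over α = 0, and the worst distilled
per-horizon error at 50 bins stays below 12 bin-index units. Two caveats
are worth stating plainly. First, standardized inputs and Adam make this
baseline unusually stable: it never diverges, so regimes in which
distillation more than halves the error — which arise when a fragile
baseline suffers catastrophic excursions of hundreds of bin-index units at
single horizons — do not occur here. The guidance effect that remains is
the moderate, consistent kind, not the rescue-from-divergence kind. Second,
the per-horizon advantage is an average-over-grid property; at individual
(horizon, seed) cells the ordering can invert.

The 50-bin horizon-13 baseline cell carries an outlier *annotation* in the
emitted tables, demonstrating the annotation-only exclusion workflow:
exclusion-aware aggregates drop the cell, the raw row is never deleted, and
every exclusion is listed in the JSON summary.

## Synthetic event recordings

The generator emulates the statistical skeleton of long-term seizure EEG on
a desk scale — it is a testbed for the training machinery, not a neural
simulation:

* **Interictal background**: per-channel 1/f-shaped Gaussian noise (spectral
  shaping of white noise), unit RMS times a per-channel gain drawn in
  [0.8, 1.2].
* **Ictal events**: a 6 Hz sinusoidal burst (default 20 s) added to the
  background, scaled so the ictal/interictal RMS ratio equals the configured
  `amplitude_ratio` (default 4; verified within 10%).
* **Preictal period** (default 600 s before each onset; truncated only at
  recording start): a ramped variance drift (up to `1 + 0.3κ`) plus a ramped
  low-amplitude oscillation at the ictal frequency (up to `0.4κ`), both
  scaled by the effect size κ. κ = 0 yields a null task — preictal is
  generatively identical to interictal and any classifier's expected AUC
  is 0.5.
* **Broadband artifacts**: short Hann-tapered white-noise bursts (default
  1/min, 3× RMS) scattered independently of state. They decouple "high
  power" from "event", which is what gives the detector's *narrowband*
  knowledge value beyond what raw amplitude provides — as in real EEG, where
  movement artifacts dwarf many seizures in amplitude.

Segment labeling tiles fixed-length windows within maximal constant-state
runs (no window straddles a boundary; runs shorter than the window are
dropped and counted). The detection task keeps ictal vs interictal windows
and **excludes every preictal window, with the exclusion count reported** — a
detector trained on preictal data would be too certain near events,
destroying exactly the uncertainty the student needs distilled. The
prediction task keeps preictal vs interictal. Top-k channel selection ranks
channels by the absolute standardized mean difference (pooled-SD Cohen's d)
of log window power between event and background windows, ties toward the
lower index; it reconciles channel dimensionality when a universal
(out-of-distribution) teacher supervises a student with a different montage.

**Event benchmark protocol** (subject-specific): one recording per replicate
(1600 s, 32 Hz, 4 channels, 2 events, 120 s preictal horizon, κ = 1,
artifacts 2/min at 3× RMS), split chronologically in half — the first event
trains, the second tests. The scarcity is deliberate: the student learns the
preictal signature of a *single* event, which makes its performance unstable
across seeds, while the detection teacher's knowledge comes from high-SNR
ictal windows and does not depend on preictal examples at all. This is the
regime in which near-future guidance has something to offer, and it matches
the motivating observation that few events per subject destabilize
forecasting models. Under these conditions the distilled student's test AUC
matches or beats the baseline in at least 4 of 5 seeds with a smaller spread,
and at κ = 0 both sit at chance. With abundant events, or when evaluating
across recordings with different channel gains, the teacher's transferred
ranking no longer exceeds a competent baseline and the advantage vanishes —
distillation is not a free lunch, and the package makes that regime boundary
easy to explore.

Benchmark event models train with Adam 1e−3 (teacher 50 epochs, student 25).
`RunConfig.event_default()` instead carries settings typical of
patient-specific EEG detector work (SGD 5e−4, τ = 4, 50 teacher / 25 student
epochs, aligned teacher view); those suit much larger recurrent-convolutional
models and underfit the compact networks used here, so the benchmark
overrides them.
The aligned teacher view (teacher scores the student's own window) is the
default in event mode; the temporally offset view used in regression mode is
available as `teacher_view="offset"`.

## Evaluation and reporting

AUC-ROC uses the Mann-Whitney formulation (ties count ½; cross-checked
against exhaustive pair counting). Sensitivity and FPR are computed at
`score ≥ threshold` and are non-increasing in the threshold. Result tables
are tidy per-(horizon, variant, seed) records; aggregates are means of
per-horizon seed means, outlier handling is annotation-only, and every
summary is exactly reproducible from the emitted CSV. Replicates default to
three seeds per configuration with mean and variance reported.

## Determinism

Every stochastic component — trajectory generation, recording synthesis,
model initialization, batch order — derives from explicit integer seeds
through `numpy` generators; no global random state is touched. A full
simulate→train→evaluate run is bit-reproducible on a fixed platform, and
teacher checksums are recorded in run metadata.

## Known limitations

* Encoders are small MLPs; recurrent/convolutional families, GPU training,
  learning-rate schedules and early stopping are out of scope.
* The event generator does not model real EEG nonstationarity, montage
  geometry, artifact taxonomies or inter-subject variability beyond channel
  gains; passing tests show the machinery behaves as designed, not that any
  particular clinical performance would be reached. The optional EDF loading
  path for real recordings is intentionally not wired into the benchmarks.
* Binning is equal-width only (no quantile/adaptive binning or
  mixture-density decoding).
* The chained multi-horizon variant reports per-link KL diagnostics but has
  no benchmark of its own.
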