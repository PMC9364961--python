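# Methods

This note documents the models, procedures and numerical choices behind
`somnostage`: what the synthetic polysomnography generator emulates, how the
parallel CNN-LSTM stager is built and trained, how the evaluation metrics
and the Hilbert-Huang analysis are defined, and where the open design
decisions were resolved.

## Sleep staging problem

Overnight recordings are scored in 30-s epochs, each assigned one of the
five AASM stages: W (wake), N1, N2 (light sleep), N3 (deep sleep) and REM.
The classifier input is one epoch of two channels, EEG and EOG, in that
fixed order. Stage assignment rests on rhythm content and transients:

| stage | EEG background | transients |
|---|---|---|
| W | alpha 8–13 Hz, 20–100 µV | eye blinks (EOG) |
| N1 | theta 4–8 Hz, 20–150 µV; alpha share < 50 % | — |
| N2 | theta with emerging delta | spindles 12–14 Hz; K-complexes (> 0.5 s, biphasic) |
| N3 | slow delta 0.5–2 Hz, 20–200 µV (> 20 % delta share) | — |
| REM | theta + irregular alpha | sawtooth 2–7 Hz (EEG); rapid eye movements (EOG) |

## Synthetic generator

Each stage is a `StageSpec`: a list of oscillatory components
(band, amplitude range, mixing weight), a list of transient events, and a
broadband-noise level. An epoch is synthesized as

1. **Background** — each component is a randomized-phase narrowband signal
   (inverse FFT of unit spectrum over the band with uniform random phases),
   normalized to unit RMS and scaled to an effective sinusoid amplitude
   `w_i · a_i` where `w_i` are the weights renormalized to sum to one and
   `a_i` is drawn in the component's amplitude range. The amplitude draws
   share one per-epoch level `u ~ U(0,1)` with ±10 % per-component jitter:
   overall EEG amplitude varies epoch to epoch while the *relative* band
   structure stays stage-determined (this is what makes the per-stage
   dominant-band property hold with margin).
2. **Transients** — Poisson counts per epoch at the configured rate.
   Spindles and sawtooth waves are Gaussian-enveloped carrier bursts with
   the carrier drawn in their band; K-complexes, blinks and rapid eye
   movements are biphasic negative-then-positive pulses (one Hann-windowed
   sine cycle). Durations jitter ±25 % around the nominal value (K-complex
   nominal 0.8 s, staying above the defining 0.5 s). Event peak amplitude
   defaults to 1.5× the epoch's realized mean background amplitude, so
   transients stay proportionate to the rhythms they ride on.
3. **Noise** — white Gaussian, with sd defaulting to 10 % of the dominant
   component's mean amplitude.

Oscillatory components render on the EEG channel; events target their
configured channel; both channels receive independent noise. Generation
runs at 100 Hz (resolving spindles and beta); only the model path decimates.

Nights are laid out by a semi-Markov hypnogram model: geometric bout
lengths with per-stage means (default 1.5–7.5 min), bout-entry weights
proportional to `target fraction / mean bout length`, so empirical stage
fractions converge to the configured proportions. Default proportions take
the midpoints of the reported clinical ranges (N1 7.5 %, N2 49.5 %,
N3 15 %), REM at the low end (22 %) of its unusually wide quoted 20–50 %
range, wake absorbing the remaining 6 %.

**What the generator does not emulate:** 1/f spectral slope, electrode and
movement artifacts, inter-subject variability of rhythm frequencies,
arousals, EMG/ECG contamination. Passing tests therefore demonstrate that
the pipeline learns and scores *separable* stage classes correctly — not
clinical-grade performance on real polysomnography.

## The parallel CNN-LSTM stager

The canonical input is 300 × 2: a 30-s epoch at the 10 Hz model rate
(100 Hz generation data is anti-alias FIR-decimated by 10). Raw microvolt
values are divided by a fixed constant of 100 µV on entry — a documented
unit convention, not a data-dependent normalization — so gate activations
start order-one.

Two branches see the same input:

* **LSTM branch** — two stacked 64-unit LSTM layers (standard gated
  recurrence: forget/input/output sigmoid gates, tanh candidate,
  `c_t = f⊙c_{t-1} + i⊙c̃`, `h_t = o⊙tanh(c_t)`); the first emits its full
  300 × 64 hidden sequence, the second its final 64-vector. An optional
  softmax attention pooling over the second layer's sequence is provided
  but off by default (the canonical model concatenates the last hidden
  state).
* **CNN branch** — conv(64 filters, kernel 5, valid, stride 1) → batch
  norm → ReLU → dropout(0.2) → max-pool(3, stride 3) → conv(32, 5) → batch
  norm → ReLU → dropout → max-pool(3) → flatten. Temporal lengths:
  300 → 296 → 98 → 94 → 31; flatten width 31 × 32 = 992.

Concatenation (992 + 64 = 1056) feeds FC 64 (ReLU, dropout 0.5) → FC 32
(ReLU, dropout 0.5) → softmax over the five stages; prediction is the
argmax. `shape_trace` computes this dimension list from any configuration
without instantiating parameters, and the realized forward pass is
contract-tested against it.

Initialization: Glorot-uniform weights, zero biases except the LSTM forget
gate (bias 1, the standard open-at-start choice), and a zero-initialized
output layer so an untrained model scores all stages uniformly at 0.2.

### Implementation notes

The network is implemented directly on numpy (float32 batches), with exact
backpropagation — verified against central-difference gradients (max
relative error ≈ 5 × 10⁻⁷) and, for the LSTM, against a float64 per-gate
reference cell. The LSTM step loop is engineered for single-core
throughput: time-major preallocated buffers reused across batches, the
input projection written straight into the gate buffer by one matrix
product, per-step recurrent products accumulated in place via BLAS
`sgemm(beta=1)` on transposed views, the three sigmoids folded into a
single whole-row `tanh` by pre-scaling the i/f/o parameter columns by ½,
and the remaining elementwise step arithmetic numba-compiled.
Transcendentals stay in vectorized numpy. A pure-numpy fallback implements
the identical contract. Max-pool winners are found by an explicit
comparison chain (first maximum wins, matching argmax semantics); dropout
masks are drawn at 8-bit resolution (keep probability quantized to the
nearest 1/256, with the inverted-dropout scale using the realized value).

## Training regimen

* **Splitting** is by whole subject, never by epoch; within-subject
  temporal order is preserved. Night-level cross-validation folds are
  contiguous in stored order (48 nights / 12 folds → exactly 4 each).
* **Rebalancing**: stage frequencies are heavily skewed toward N2, so per
  (night, stage) group the epoch count is capped (canonical cap 200):
  larger groups are sampled down without replacement; smaller groups of the
  minority stages (W, N1, N3, REM) keep all originals and add duplicates
  drawn with replacement up to the cap.
* **Optimizer**: plain minibatch SGD (no momentum) on softmax
  cross-entropy, learning rate `lr(e) = 0.015 · 0.1^⌊e/20⌋`, canonical
  batch 10, 100 epochs. Global-norm gradient clipping (default 5.0) guards
  the 300-step backpropagation through time; a non-finite loss aborts with
  a diagnostic. Fixed seed + single thread ⇒ bit-reproducible runs.

## Separability benchmark

`separability_benchmark` is the package's end-to-end check: 12 subjects ×
1 night × 600 epochs at the default recipes, the last 2 subjects held out
entirely, training nights rebalanced to 75 epochs per stage (the same
mechanism as the canonical policy with a tighter cap, keeping the run at
desk scale: 3 750 training epochs, a few minutes on one CPU), and the
canonical model trained 30 epochs at batch 128. The step size is the
canonical 0.015 rescaled linearly to the benchmark batch
(0.015 × 128/10 = 0.192), the standard large-batch SGD adjustment. Scoring
the 1 200 held-out epochs yields accuracy and macro-F1; the acceptance
suite requires ≥ 0.85 and ≥ 0.80. Again: this certifies the
generator-learner loop, not clinical accuracy.

## Evaluation metrics

From the 5 × 5 confusion matrix (rows true, columns predicted, stage order
W, N1, N2, N3, REM): per class one-vs-rest `PRE = TP/(TP+FP)`,
`REC = TP/(TP+FN)`, `F1 = 2·PRE·REC/(PRE+REC)`; overall `ACC` =
trace/total; `MF1` = unweighted mean of the five F1 values. Zero-division
convention: empty predicted class ⇒ PRE = 0; absent true class ⇒ REC =
F1 = 0 and still averaged into MF1 by default (configurable). Reports
print percentages; the API returns fractions.

## Hilbert-Huang analysis

`emd` implements classic sifting: cubic-spline envelopes through maxima
and minima (mirror-extending two extrema past each end against spline end
effects), mean-envelope subtraction iterated until the Cauchy criterion
`Σ(mean env)² / Σh² < 0.2` *and* the IMF extrema/zero-crossing property
(counts differing by at most one) hold, at most 50 siftings per mode and 8
modes, stopping when the remainder is monotone. Because each IMF is
literally subtracted, IMFs + residual reconstruct the input to floating
point exactly.

`instantaneous_frequency` differentiates the unwrapped analytic-signal
phase (`scipy.signal.hilbert`), scales by fs/2π, trims 5 % of samples at
each edge, clamps negative values (phase-unwrapping noise) to zero and
counts them. `stage_frequency_histograms` pools the IF samples of the
first four IMFs per stage into 50-bin densities over 0–30 Hz (the
clinically considered EEG band), excluding clamped samples; each IMF's
histogram is count-based and normalized to unit integral, so fast
low-energy modes (broadband noise) weigh equally with slow high-energy
ones — an amplitude-weighted variant (a Hilbert marginal spectrum) is
deliberately out of scope.

`relative_band_energy` integrates the periodogram over the canonical
δ/θ/α/β bands and normalizes over their union.

## I/O conventions

Generated nights export as standard EDF (1-s records, int16, symmetric
physical scaling in µV) plus a plain-text hypnogram sidecar
(`epoch_index<TAB>stage` per line, 0-based, gap-free; unknown tokens such
as the six-stage "N4" are rejected). Reading goes through MNE's EDF parser
— an independent implementation, which makes the round-trip test
meaningful; round-trip error is bounded by half a 16-bit quantization
step. Epochs are half-open windows `[t, t+30)`. Model checkpoints are
single-file `.npz` archives with the configuration embedded and a format
version tag.

## Known limitations

* The generator's stages are more separable than real sleep; reported
  benchmark numbers say nothing about real-data accuracy.
* At the 10 Hz model rate, alpha/spindle/beta content is removed by the
  anti-alias filter; the model distinguishes W/N1/REM largely through
  low-band power and EOG morphology. The generation-rate (100 Hz) data
  retains all bands for the Hilbert-Huang path.
* EMD is the classic single-realization algorithm; mode mixing is not
  addressed (no ensemble variants).
* The EDF writer covers continuous two-channel recordings only (no
  annotations, no discontinuous records).
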