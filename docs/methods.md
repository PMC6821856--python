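# Methods

## Model and pipeline

The pipeline classifies 5-minute multichannel iEEG stretches as preictal or
interictal in five stages: (1) zero-phase band-pass (0.5–180 Hz) and 60 Hz
notch filtering; (2) segmentation into balanced, labeled 60-min hours and
30-s non-overlapping windows, standardized to zero mean and unit variance;
(3) direct-method bispectrum estimation per window and channel, reduced to
the two entropies E1 and E2 over the non-redundant region Ω; (4) assembly of
10-step × 32-feature sequences and a temporal seizure-per-seizure 40/30/30
split; (5) a single-layer LSTM trained with Adam and cross-entropy,
evaluated by sensitivity/specificity/accuracy with preictal positive.

Assumptions worth stating explicitly: the preictal state is taken to span
exactly 60 minutes ending 5 minutes (intervention time) before onset;
seizures without 65 minutes of uninterrupted history are excluded;
interictal data must lie at least `interictal_gap_h` (default 4 h) from
every onset; classes are balanced by sampling one interictal hour per
usable seizure.

## Bispectrum estimation

The estimator is the classical direct method. A 30-s window is split into
records of `record_len` samples with `overlap_fraction` overlap (defaults
4096 and 0.5 → 4 records at 400 Hz), each record is mean-detrended, Hann
tapered, transformed at `nfft = 4096` points, and the triple product
`X(f1+f2) X*(f1) X*(f2)` is averaged over records and scaled by
`1/record_len`. Notes:

- `nfft` is restricted to powers of two; 4096 gives the familiar
  4096 × 4096 density grid at 400 Hz. The magnitude of the triple product is
  unaffected by which of the two conventional conjugation patterns is used.
- The sum-frequency index is computed modulo `nfft` over the full grid; the
  features read only Ω, so aliased far corners never contribute.
- Ω is the full principal triangle `0 ≤ n ≤ m, m + n ≤ nfft/2` up to
  Nyquist; the preceding band-pass already suppresses out-of-band energy, so
  Ω is not additionally trimmed to the filter band.
- The grid is exactly symmetric under `f1 ↔ f2` by construction, and for
  small `nfft` the implementation agrees with a naive triple-loop evaluation
  to ~1e-14 relative error (tested at ≤ 1e-10).
- `principal_domain_direct` accumulates the identical averages only at the
  Ω bins (an algebraically exact restriction, ~15× cheaper at `nfft` 256);
  the test suite asserts equality with the full-grid route, and the feature
  path uses it.

Entropies use the natural logarithm with `0·log 0 := 0`, so
`0 ≤ E1, E2 ≤ ln L` with `L = |Ω|`; no division by `ln L` is applied — the
entropies feed scale-tolerant classifiers, and the un-normalized convention
keeps the uniform case at `ln L` exactly. An all-zero window (possible only
for identically zero input) is an explicit error rather than a silent 0/0.

## Preprocessing choices

Filtering is forward–backward (zero-phase): a 4th-order Butterworth
band-pass and a Q = 30 IIR notch. Zero-phase filtering is essential here —
a causal IIR filter's phase response would distort the very phase relations
the bispectrum measures. Standardization uses the population (ddof = 0)
convention and is applied per channel per 30-s window by default (the most
local scope, making features amplitude-invariant window by window); a
config switch (`standardize_scope: hour`) applies it per hour instead.
Interictal hours are sampled on an hour grid (seeded) so chosen hours are
disjoint by construction.

## Synthetic data

Each channel is built from 4096-sample sub-epochs. Per sub-epoch:
`cos(2πf1 t + φ1) + cos(2πf2 t + φ2) + λ cos(2π(f1+f2) t + φ3)` plus
Gaussian `1/f^β` noise, with `φ1, φ2` fresh uniform draws and
`φ3 = φ1 + φ2` in coupled (preictal) stretches or independent otherwise.
Defaults: `f1 = 25 Hz`, `f2 = 50 Hz` (both on bin centers at every
power-of-two `nfft` used), `λ = 1.5`, SNR 10 dB, `β = 1`, 16 channels at
400 Hz sharing the coupled state but with independent noise and phases.
Phases are redrawn per sub-epoch so the estimator's record averaging sees
independent realizations; sub-epochs equal the default record length.
Samples are stored float32 (hours of 16-channel 400 Hz data; quantization
is irrelevant at the feature level).

What the generator emulates: the second-order indistinguishability of the
two classes (identical power spectra, verified by test), the bispectral
separability, the preictal/interictal timeline and balancing. What it does
not emulate: seizure morphology, artifacts, nonstationary background,
channel covariance, or any physiological preictal dynamics — passing tests
show the pipeline detects QPC structure under the stated conditions, not
that real preictal iEEG contains such structure. Coupling is constant
across the preictal span (no ramp), the simplest assumption absent evidence
for a specific temporal profile.

The scaled profile used by the worked example, tests and the acceptance
script keeps every structural condition (16 channels, 400 Hz, 65-min
preictal history, 5-min horizon, 120 windows/hour, 10-step sequences,
40/30/30 split) and shrinks the study to 3 seizures with a 1.25 h
interictal gap and an nfft-256 estimator, i.e. a ~13 h subject and 72
sequences. The gap must remain longer than the 65-min preictal span:
with a shorter gap an "interictal" hour can overlap a later seizure's
coupled span and contaminate the labels (the 4 h default makes this
impossible at full scale).

## Classifiers

LSTM: standard gate equations (input/forget/candidate/output), zero initial
states, classification from the final hidden state only. Initialization is
Glorot-uniform for input and recurrent kernels, zero biases with the
forget-gate bias at 1 (keeps early memory open). Training: cross-entropy,
Adam (β₁ = 0.9, β₂ = 0.999, ε = 1e-8), initial learning rate 1e-3 dropped
by 0.1 every 50 epochs, minibatches of 24 reshuffled each epoch (seeded),
hard stop at `max_iterations` minibatch updates with no early stopping.
"Iteration" always means one minibatch update and "epoch" one full pass;
both appear in the training log since the two are easy to conflate.
Divergence (non-finite loss) aborts with the log retained. Runs are
deterministic given the seed on a single thread.

MLP baseline: scikit-learn `MLPClassifier` (hidden 30/60/30, ReLU, SGD,
lr 1e-3) driven by an explicit minibatch `partial_fit` loop so early
stopping (patience 10 epochs) monitors the pipeline's own validation slice
rather than an internal random split; inputs are per-window 16-vectors of a
single feature, scaled by training-slice mean/std.

Split sizes use round-half-up of `0.4·S` and `0.3·S` (so S = 17 → 7/5/5,
S = 10 → 4/3/3); at least 3 seizures are required. Sequences tile each hour
without overlap (12 per hour); an overlap option was deliberately not
added — per-hour sequence counts then stay interpretable.

## Evaluation

Sensitivity, specificity and accuracy are computed from confusion counts
with preictal positive. Cross-subject aggregation is the unweighted mean
(each subject counts equally regardless of seizure count), displayed with
half-up rounding to 2 decimals. On a balanced set `Acc = (SS + SP)/2`; when
a set is imbalanced the report flags it instead of reconciling the numbers.
An absent class makes its rate undefined — flagged, not silently dropped.

## Known limitations

- The generator's stationarity and constant coupling make the synthetic
  classification task easier than clinical data; accuracies near 100% on it
  bound the implementation, not clinical performance.
- The EDF writer covers the subset of the format the pipeline needs
  (16-bit, one-second records, integer sampling rates); reading is
  delegated to mne and cross-checked against the writer in tests.
- No post-processing/regularization of classifier outputs and no clinical
  alarm metrics (prediction horizon, time in warning, false-prediction
  rate) are implemented; the evaluation stops at segment classification.
- Channel selection, artifact rejection and streaming ingestion are out of
  scope.
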