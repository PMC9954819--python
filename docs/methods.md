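# Methods

## The detection problem

Scalp EEG of people with epilepsy alternates between long interictal
stretches of background activity and short ictal episodes whose hallmark
is high-amplitude rhythmic discharge (classically a ~3 Hz spike-and-wave
pattern). The package frames seizure detection as binary classification of
short fixed-length windows (1, 2 or 4 s) of a multichannel recording:
label 1 if the window lies inside a seizure, 0 otherwise.

## Model

Each window is treated as a single-plane image of shape
`n_channels x (fs * window)` (electrodes by time). A deep convolutional
autoencoder (DCAE) compresses it:

* **Encoder** — four [conv 3x3, ReLU, same padding] + [max-pool 2x2]
  pairs with 32, 32, 64, 64 filters. For a 23 x 1024 input (4-s window at
  256 Hz) the bottleneck is 1 x 64 x 64: electrode axis fully collapsed,
  time axis reduced 16-fold, 64 feature maps.
* **Decoder** — four [conv 3x3] + [nearest-neighbour upsample 2x2] pairs
  with 64, 32, 32, 1 filters and a final sigmoid, so reconstructions live
  in the [0, 1] range of the min-max-scaled inputs. Each upsampling stage
  is fitted (bottom/right crop or edge-replicating pad) to the matching
  encoder stage's pre-pooling shape, undoing floor losses exactly; the
  round trip restores the input shape for every supported window length.
* **Head** — the bottleneck is read as a sequence along the reduced time
  axis (64 steps of 64 features for a 4-s window) and fed to a
  bidirectional LSTM with 80 units per direction; per-step outputs are
  averaged over time, passed through a dense layer of 50 ReLU units with
  dropout 0.75, and a 2-way softmax. `mlp` (flatten + dense) and
  unidirectional `lstm` heads are provided for comparison, as is a "DCNN"
  baseline: the same encoder + head without the decoder and without a
  reconstruction objective.

**Pooling convention.** The time (width) axis pools by strict floor
division and must remain >= 1 through all four stages; otherwise building
the model raises a shape error (e.g. an 8 x 8 input is rejected). The
electrode (height) axis also pools by floor but passes through unchanged
once it reaches 1, so montages with fewer than 16 electrodes (2^4) remain
usable; with 23 electrodes the schedule is 23 - 11 - 5 - 2 - 1 either way.

**Head order switch.** Descriptions of this architecture family sometimes
place an average-pooling layer *after* the fully connected layer; applied
literally to a dense layer's vector output that operation is a no-op, so
the default here pools over time *before* the dense layer. The literal
order (per-step dense, then temporal averaging) is available via
`avg_pool_after_dense=True`.

**Initialization.** Uniform fan-in initialization
(U(-1/sqrt(fan_in), 1/sqrt(fan_in))) for all weights, zero biases except
the LSTM forget gate (+1), all seeded; two models built with the same
configuration are bit-identical.

## Training

The autoencoder variants optimize the joint objective

    L = CE(y, p) + lambda * MSE(x, x_hat)

with both terms batch-averaged and `lambda = 1` by default; training is
single-phase (both objectives from the first step). A two-phase mode
(reconstruction-only pretraining for `epochs // 2`, then joint training)
exists behind a flag for ablation. Defaults follow the reference
configuration: Adam, learning rate 1e-4, batch size 50, 40 epochs,
cross-entropy computed from logits through a numerically stable fused
softmax with the true-class probability clamped at 1e-7 (a confidently
wrong prediction yields a large but finite loss). Two stopping rules are
available: patience on validation loss, and `stop_at_train_accuracy`,
which ends training once the model classifies its own training set at a
target accuracy without dropout (used by the benchmark protocol below).
A non-finite loss aborts with the offending epoch and batch index.

The numerical core is a small numpy layer library (`deepeeg.nn`) written
for exactly this architecture: convolutions are computed as sums of
kernel-shift BLAS matmuls (memory traffic stays proportional to the
tensor size), max-pooling tracks argmax indices for its backward pass,
and the LSTM uses full backpropagation through time. Every layer's
analytic gradient is verified against central finite differences in the
test suite. Parameters are float32 by default; float64 is available for
verification.

## Preprocessing

* **Segmentation**: contiguous non-overlapping windows starting at t = 0;
  the trailing remainder is discarded. A window is labeled ictal only if
  fully inside an annotated seizure interval (half-open, seconds from
  record start) and interictal only if fully outside all of them;
  boundary-straddling windows are dropped. This keeps labels noise-free
  at the cost of a few windows per seizure.
* **Normalization**: per-channel z-score over the pooled segments,
  then global min-max to [0, 1]. Statistics are fitted on training folds
  only and applied (with clipping) to held-out folds — pooling statistics
  across all data before splitting would leak fold information, so the
  leakage-free variant is the default; pooled fitting can be reproduced
  by normalizing before splitting.
* **Balancing**: the majority class is undersampled uniformly at random
  (seeded, without replacement) to the minority count.

## Evaluation

All five metrics (accuracy, sensitivity/recall, precision, specificity,
F1) derive from the confusion matrix with ictal as the positive class.
Metrics with zero denominators are reported as undefined (`None`), never
as 0. Formatted output rounds half-up to one decimal; full precision is
retained internally. Cross-validation is stratified k-fold (default
k = 10) with per-fold normalization and freshly initialized models; the
headline numbers are the unweighted mean of per-fold metrics, with the
pooled confusion matrix also reported.

On the published 4-s confusion counts (tp = 1772, tn = 723, fp = 1,
fn = 4) these formulas give accuracy 99.8 and specificity 99.9 at
one-decimal rounding, and sensitivity 99.8, precision 99.9, F1 99.9 —
slightly above the table values reported alongside those counts
(99.7 / 99.8 / 99.6), which are not mutually consistent with the counts
themselves. The implementation computes from the definitions and leaves
the discrepancy visible rather than matching both.

## Synthetic EEG generator

The simulator exists so that every pipeline stage, including EDF
ingestion, is testable without clinical recordings. It emulates:

* **Background**: per-band filtered Gaussian noise in the canonical bands
  (delta 0.5-4, theta 4-8, alpha 8-13, beta 13-30, gamma 30-45 Hz; gamma
  capped below Nyquist at 256 Hz), mixed across channels by a random
  orthogonal matrix (giving realistic inter-channel correlation) plus a
  phase-locked sinusoidal alpha component. Default relative band powers
  (delta 1.0, theta 0.7, alpha 0.8, beta 0.3, gamma 0.1) resemble a
  drowsy pediatric recording; overall scale 30 uV RMS.
* **Seizures**: an amplitude-modulated spike-and-wave train (Gaussian
  spike plus slow sinusoid per cycle, default 3 Hz) with a Tukey envelope
  and random per-channel gains, scaled so in-seizure RMS is
  `ictal_amp_gain` (default 5) times the background RMS.
* **Artifacts**: EMG (band-limited 20-60 Hz noise, all channels),
  eye blinks (sparse 500-ms sub-2-Hz bumps on designated frontal
  channels), and i.i.d. Gaussian white noise.

What it does **not** emulate: electrode geometry and volume conduction,
nonstationary background (sleep stages, drowsiness cycles), preictal
changes, seizure morphology diversity, electrode artifacts
(pops, detachment), or line noise. Passing tests on this data
demonstrate that the implementation learns and evaluates correctly on a
separable two-class signal-detection problem; they do not certify
clinical-grade performance on real EEG, which the source recordings
(not redistributable here) would be required to measure.

Determinism: every generator draws from `numpy` Generator streams derived
from a cohort seed and record index, so cohorts are reproducible
independent of generation order.

## Benchmark protocol

The standard benchmark is 400 balanced 4-s segments at 256 Hz from
8-channel synthetic cohorts with `ictal_amp_gain = 5`, evaluated by
stratified 5-fold cross-validation of the full-size DCAE + Bi-LSTM.
A band-power logistic regression (Welch log band powers, standardized,
sklearn `LogisticRegression`) serves as the independent oracle: it
cross-validates at ~100% on the same segments, certifying that the task
is linearly separable in spectral feature space — a detector that fails
it has an implementation problem, not a data problem.

Benchmark training uses a compressed schedule chosen for a single-CPU
run: Adam at learning rate 5e-4 (raised from the 1e-4 production default
to compensate for the short schedule), batch 50, and
`stop_at_train_accuracy = 0.995` with an epoch cap, since the epoch at
which a given initialization escapes the initial one-class plateau varies
by a few epochs across seeds. Problem sizes throughout the test suite
(segment counts, channel counts, epochs) are chosen so the whole suite
runs on one CPU in minutes while still exercising the full-size
architecture where the claim concerns it.

## Known limitations

* The reference description leaves several architectural details open
  (kernel size, pooling geometry, conv padding, the bottleneck-to-sequence
  mapping, the reconstruction loss weight); the choices here (3x3 kernels,
  2x2 pools, same padding, time-axis sequencing, lambda = 1) are the
  minimal standard ones and are recorded in `ModelConfig` defaults.
* Reported batch size differs between sources (50 vs 10); 50 is the
  default, configurable.
* "Augmentation by downsampling" in the source description is ambiguous
  (decimation? majority undersampling?) and is not implemented beyond
  majority-class balancing.
* Training is CPU-bound numpy; it is adequate for the benchmark scale
  (hundreds of segments) but not for corpus-scale experiments.
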