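# deep-eeg

Seizure detection from multichannel scalp EEG with a deep convolutional
autoencoder (DCAE) and a bidirectional LSTM classifier — plus everything
needed to exercise the pipeline end to end without clinical data: EDF and
seizure-annotation I/O, a synthetic EEG simulator with seizures and
artifacts, segmentation/normalization/balancing, joint
reconstruction-classification training, and cross-validated diagnostic
metrics.

## Who this is for

Researchers and engineers prototyping automatic epileptic-seizure
detection on 256-Hz multichannel scalp EEG (CHB-MIT-style corpora: EDF
files with plain-text seizure-time summaries), and anyone who needs a
self-contained, fully seeded testbed for window-level EEG classifiers.

## The model

EEG is cut into non-overlapping windows of 1, 2 or 4 s. Each window is an
electrode-by-time plane `x ∈ [0,1]^{N×L}` (after per-channel z-scoring and
global min-max scaling). A convolutional autoencoder compresses it:

* encoder: 4 × [conv 3×3 (32, 32, 64, 64 filters), ReLU, max-pool 2×2],
  mapping 23×1024 (4-s window) to a 1×64×64 bottleneck `z`;
* decoder: 4 × [conv (64, 32, 32, 1 filters), upsample 2×2], sigmoid
  output `x̂` of the input shape;
* head: `z` read as 64 time steps of 64 features → Bi-LSTM (80 units per
  direction) → temporal average pooling → dense(50, ReLU) →
  dropout 0.75 → softmax over {interictal, ictal}.

Training minimizes the joint objective

```
L = CE(y, p) + λ · MSE(x, x̂),        λ = 1
```

with Adam (lr 1e-4, batch 50 by default). MLP and unidirectional LSTM
heads and a DCNN baseline (encoder + head, no decoder) are included for
comparison. Evaluation derives accuracy, sensitivity, precision,
specificity and F1 from the confusion matrix (ictal = positive) under
stratified k-fold cross-validation with per-fold normalization.

The numerical core is a compact numpy layer library (`deepeeg.nn`) with
analytic gradients, verified against finite differences in the test
suite; no GPU or deep-learning framework is required.

## Worked example

Published 4-s-segment confusion counts (tp=1772, tn=723, fp=1, fn=4)
through the metric formulas:

```
$ deep-eeg metrics --from-confusion 1772,1,4,723
metric  accuracy  sensitivity  precision  specificity    f1
------  --------  -----------  ---------  -----------  ----
 value      99.8         99.8       99.9         99.9  99.9
```

Accuracy 99.8% = (1772+723)/2500; specificity 99.9% = 723/724, rounded
half-up to one decimal. (These counts are slightly inconsistent with the
F1/precision values printed alongside them in the source table; the
package computes from the definitions — see `docs/methods.md`.)

A fully synthetic end-to-end run:

```
$ deep-eeg synth --n-records 6 --seizure-fraction 0.5 --duration 60 \
      --n-channels 8 --seed 7 --out-dir cohort
wrote 6 EDF files (3 with seizures) to cohort

$ deep-eeg segment --window 4 --balance --seed 0 --in-dir cohort --out segs.npz
segmented: 86 windows (7 ictal / 79 interictal)
balanced to 14 windows
wrote segs.npz
```

`deep-eeg train` and `deep-eeg crossval` then fit and evaluate any of the
four model variants (`dcae-bilstm`, `dcae-lstm`, `dcae-mlp`, `dcnn-mlp`)
on such a dataset. The same functionality is available as a scikit-learn
estimator:

```python
from sklearn.pipeline import Pipeline
from deepeeg import DCAEClassifier, SegmentScaler

pipe = Pipeline([("scale", SegmentScaler()),
                 ("clf", DCAEClassifier(head="bilstm", epochs=16))])
pipe.fit(X, y)          # X: (n_segments, n_channels, n_samples)
pipe.predict_proba(X)
```

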