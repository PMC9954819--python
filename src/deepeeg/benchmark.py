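"""The standard synthetic seizure-detection benchmark and its oracle.

The benchmark is a balanced set of 4-s, 8-channel segments cut from
synthetic recordings whose seizures have five times the background
amplitude.  A band-power logistic-regression baseline certifies that the
benchmark is linearly separable in spectral feature space; any competent
detector should therefore approach perfect accuracy, and a large shortfall
indicts the detector rather than the data.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sps
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .preprocess import SegmentSet, segment_recordings
from .synth import BANDS, SynthSpec, generate_labeled_dataset

__all__ = [
    "make_benchmark_segments",
    "benchmark_model_config",
    "benchmark_train_config",
    "band_power_features",
    "band_power_logistic",
    "band_power_cv_accuracy",
]


def make_benchmark_segments(
    n_segments: int = 400,
    n_channels: int = 8,
    segment_length_s: float = 4.0,
    ictal_amp_gain: float = 5.0,
    fs: float = 256.0,
    seed: int = 0,
) -> SegmentSet:
    """Balanced labeled segments from a seeded synthetic cohort.

    Records of 60 s, each with one seizure, are generated in chunks until
    both classes have ``n_segments // 2`` members; the result is shuffled
    deterministically.
    """
    per_class = n_segments // 2
    record_s = 60.0
    ictal_parts, inter_parts = [], []
    n_ictal = n_inter = 0
    chunk = 0
    while (n_ictal < per_class or n_inter < per_class) and chunk < 64:
        spec = SynthSpec(
            fs=fs,
            n_channels=n_channels,
            ictal_amp_gain=ictal_amp_gain,
            seed=int(np.random.default_rng(
                np.random.SeedSequence([seed, 977, chunk])
            ).integers(0, 2**31 - 1)),
        )
        records = generate_labeled_dataset(
            spec, n_records=20, seizure_fraction=1.0, duration_s=record_s
        )
        segs = segment_recordings(records, segment_length_s)
        ictal_parts.append(segs.subset(segs.labels == 1))
        inter_parts.append(segs.subset(segs.labels == 0))
        n_ictal += len(ictal_parts[-1])
        n_inter += len(inter_parts[-1])
        chunk += 1
    if n_ictal < per_class or n_inter < per_class:
        raise RuntimeError("benchmark generation failed to reach class counts")

    tensor = np.concatenate(
        [np.concatenate([p.tensor for p in ictal_parts])[:per_class],
         np.concatenate([p.tensor for p in inter_parts])[:per_class]]
    )
    labels = np.concatenate(
        [np.ones(per_class, dtype=int), np.zeros(per_class, dtype=int)]
    )
    rng = np.random.default_rng(np.random.SeedSequence([seed, 978]))
    order = rng.permutation(len(labels))
    return SegmentSet(
        tensor=tensor[order],
        labels=labels[order],
        fs=fs,
        segment_length_s=segment_length_s,
        meta={
            "benchmark": True,
            "n_channels": n_channels,
            "ictal_amp_gain": ictal_amp_gain,
            "seed": seed,
        },
    )


def benchmark_model_config(seed: int = 0):
    """Full-size DCAE + Bi-LSTM configuration for the benchmark."""
    from .models import roster_config

    return roster_config("dcae-bilstm", seed=seed)


def benchmark_train_config(seed: int = 0):
    """Training configuration used for benchmark cross-validation runs.

    A compressed single-CPU schedule: learning rate 5e-4 (raised from the
    1e-4 production default to offset the short budget), at most 16
    epochs, stopping as soon as the training set is classified at 99.5%
    accuracy without dropout.  The benchmark is strongly separable, so
    most runs stop after a handful of epochs; the explicit stop also
    guards against the occasional late-epoch regression of the joint
    objective.
    """
    from .training import TrainConfig

    return TrainConfig(
        optimizer="adam", learning_rate=5e-4, batch_size=50, epochs=16,
        stop_at_train_accuracy=0.995, seed=seed,
    )


def band_power_features(tensor: np.ndarray, fs: float) -> np.ndarray:
    """Log band power per channel and canonical band (Welch PSD)."""
    n, c, t = tensor.shape
    nperseg = min(256, t)
    freqs, psd = sps.welch(tensor, fs=fs, nperseg=nperseg, axis=2)
    feats = []
    for lo, hi in BANDS.values():
        sel = (freqs >= lo) & (freqs < hi)
        feats.append(np.log(psd[:, :, sel].sum(axis=2) + 1e-12))
    return np.concatenate(feats, axis=1)


def band_power_logistic() -> Pipeline:
    """The independent baseline: standardized band powers -> logistic fit."""
    return Pipeline(
        [
            ("scale", StandardScaler()),
            ("clf", LogisticRegression(max_iter=2000)),
        ]
    )


def band_power_cv_accuracy(
    segments: SegmentSet, k: int = 5, seed: int = 0
) -> float:
    """Stratified k-fold CV accuracy of the band-power logistic baseline."""
    X = band_power_features(segments.tensor, segments.fs)
    cv = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    scores = cross_val_score(
        band_power_logistic(), X, segments.labels, cv=cv, scoring="accuracy"
    )
    return float(scores.mean())
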