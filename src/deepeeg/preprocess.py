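"""Segmentation, normalization and class balancing of EEG recordings.

Recordings are cut into non-overlapping fixed-length windows (1, 2 or 4 s
are the standard choices).  A window is labeled ictal (1) only when it lies
entirely inside an annotated seizure interval and interictal (0) only when
it lies entirely outside all of them; windows straddling a seizure boundary
are discarded to avoid label noise.

Normalization follows the two-step scheme used for autoencoder training on
scalp EEG: per-channel z-scoring over the pooled segments,
``x' = (x - mu) / sigma``, followed by global min-max scaling of the
z-scored values to [0, 1] so that input and reconstruction share a range.
The fitted statistics are returned so held-out data can be transformed with
training-fold parameters (values outside the fitted range are clipped).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import DegenerateChannelError
from .records import EEGRecording

__all__ = [
    "NormalizationParams",
    "SegmentSet",
    "segment_recording",
    "segment_recordings",
    "zscore",
    "minmax_scale",
    "balance_classes",
    "reshape_for_model",
]

VALID_WINDOWS_S = (1, 2, 4)


@dataclass(frozen=True)
class NormalizationParams:
    """Fitted normalization statistics.

    ``mu``/``sigma`` are per-channel moments in microvolts computed over the
    pooled segments; ``global_min``/``global_max`` are the post-z-score
    extrema used by min-max scaling.
    """

    mu: np.ndarray
    sigma: np.ndarray
    global_min: float = np.nan
    global_max: float = np.nan

    def __post_init__(self):
        object.__setattr__(self, "mu", np.asarray(self.mu, dtype=np.float64))
        object.__setattr__(self, "sigma", np.asarray(self.sigma, dtype=np.float64))
        if np.any(self.sigma <= 0):
            raise DegenerateChannelError(np.nonzero(self.sigma <= 0)[0].tolist())
        if np.isfinite(self.global_min) and not self.global_min < self.global_max:
            raise ValueError("global_min must be < global_max")


@dataclass
class SegmentSet:
    """A stack of fixed-length labeled EEG segments.

    Attributes
    ----------
    tensor : ndarray, shape (n_segments, n_channels, segment_samples)
    labels : ndarray of {0, 1}, 1 = ictal
    fs : float, sampling rate in Hz
    segment_length_s : float, window length in seconds
    normalization : NormalizationParams or None
        Set once the set has been z-scored / min-max scaled.
    meta : dict, free-form provenance
    """

    tensor: np.ndarray
    labels: np.ndarray
    fs: float
    segment_length_s: float
    normalization: NormalizationParams | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.tensor = np.asarray(self.tensor)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.tensor.ndim != 3:
            raise ValueError("tensor must be (n_segments, n_channels, samples)")
        if len(self.labels) != len(self.tensor):
            raise ValueError("labels length must equal number of segments")
        expected = int(round(self.fs * self.segment_length_s))
        if self.tensor.shape[0] and self.tensor.shape[2] != expected:
            raise ValueError(
                f"segment length {self.tensor.shape[2]} samples inconsistent "
                f"with fs*segment_length_s = {expected}"
            )

    def __len__(self) -> int:
        return len(self.tensor)

    @property
    def n_channels(self) -> int:
        return self.tensor.shape[1]

    @property
    def segment_samples(self) -> int:
        return self.tensor.shape[2]

    def class_counts(self) -> tuple[int, int]:
        """(n_interictal, n_ictal)."""
        return int(np.sum(self.labels == 0)), int(np.sum(self.labels == 1))

    def subset(self, idx) -> "SegmentSet":
        return replace(self, tensor=self.tensor[idx], labels=self.labels[idx])


def segment_recording(rec: EEGRecording, segment_length_s: float) -> SegmentSet:
    """Cut a recording into contiguous non-overlapping labeled windows.

    Windows start at t = 0; the trailing remainder shorter than one window
    is discarded.  Labels: 1 if the window is fully inside an ictal
    interval, 0 if fully outside all; straddling windows are dropped.
    """
    win = int(round(segment_length_s * rec.fs))
    if abs(win - segment_length_s * rec.fs) > 1e-6:
        raise ValueError(
            f"segment_length_s * fs = {segment_length_s * rec.fs} is not an "
            "integer number of samples"
        )
    n_full = rec.n_samples // win
    if n_full == 0:
        warnings.warn(
            f"recording of {rec.duration_s:.3f} s shorter than one "
            f"{segment_length_s}-s window: empty segment set",
            stacklevel=2,
        )
    segments, labels = [], []
    for i in range(n_full):
        start_s = i * win / rec.fs
        stop_s = (i + 1) * win / rec.fs
        inside = any(iv.contains(start_s, stop_s) for iv in rec.annotations)
        outside = all(
            stop_s <= iv.onset_s or start_s >= iv.offset_s
            for iv in rec.annotations
        )
        if inside:
            labels.append(1)
        elif outside:
            labels.append(0)
        else:
            continue  # straddles a seizure boundary
        segments.append(rec.signal[:, i * win : (i + 1) * win])

    tensor = (
        np.stack(segments)
        if segments
        else np.empty((0, rec.n_channels, win))
    )
    return SegmentSet(
        tensor=tensor,
        labels=np.array(labels, dtype=np.int64),
        fs=rec.fs,
        segment_length_s=segment_length_s,
        meta={"subject_id": rec.subject_id},
    )


def segment_recordings(
    recs: list[EEGRecording], segment_length_s: float
) -> SegmentSet:
    """Segment several recordings and concatenate the results."""
    if not recs:
        raise ValueError("no recordings given")
    parts = [segment_recording(r, segment_length_s) for r in recs]
    fs = parts[0].fs
    if any(p.fs != fs for p in parts):
        raise ValueError("recordings have different sampling rates")
    return SegmentSet(
        tensor=np.concatenate([p.tensor for p in parts]),
        labels=np.concatenate([p.labels for p in parts]),
        fs=fs,
        segment_length_s=segment_length_s,
        meta={"n_recordings": len(recs)},
    )


def _fit_zscore(tensor: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # moments per channel over pooled segments and time
    mu = tensor.mean(axis=(0, 2))
    sigma = tensor.std(axis=(0, 2))
    if np.any(sigma == 0):
        raise DegenerateChannelError(np.nonzero(sigma == 0)[0].tolist())
    return mu, sigma


def zscore(
    segments: SegmentSet, params: NormalizationParams | None = None
) -> tuple[SegmentSet, NormalizationParams]:
    """Standardize each channel to zero mean, unit SD over pooled segments.

    With ``params`` given, applies those statistics instead of fitting
    (for held-out folds).  Returns the transformed set and the parameters.
    """
    if params is None:
        mu, sigma = _fit_zscore(segments.tensor)
        params = NormalizationParams(mu=mu, sigma=sigma)
    else:
        mu, sigma = params.mu, params.sigma
    z = (segments.tensor - mu[None, :, None]) / sigma[None, :, None]
    return replace(segments, tensor=z, normalization=params), params


def minmax_scale(
    segments: SegmentSet, params: NormalizationParams | None = None
) -> tuple[SegmentSet, NormalizationParams]:
    """Scale pooled values to [0, 1] (fit), or clip-transform with ``params``.

    When fitting, the pooled minimum maps to 0 and maximum to 1.  When
    transforming held-out data with fitted parameters, values outside the
    fitted range are clipped to the boundaries.
    """
    fit = params is None or not np.isfinite(params.global_min)
    if fit:
        lo = float(segments.tensor.min())
        hi = float(segments.tensor.max())
        if not lo < hi:
            raise ValueError("degenerate range: all values identical")
        base = params or segments.normalization
        if base is None:
            base = NormalizationParams(
                mu=np.zeros(segments.n_channels),
                sigma=np.ones(segments.n_channels),
            )
        params = replace(base, global_min=lo, global_max=hi)
    lo, hi = params.global_min, params.global_max
    scaled = np.clip((segments.tensor - lo) / (hi - lo), 0.0, 1.0)
    return replace(segments, tensor=scaled, normalization=params), params


def invert_minmax(tensor: np.ndarray, params: NormalizationParams) -> np.ndarray:
    """Map [0, 1]-scaled values back to the z-score scale."""
    return tensor * (params.global_max - params.global_min) + params.global_min


def balance_classes(segments: SegmentSet, seed: int = 0) -> SegmentSet:
    """Equalize class counts by undersampling the majority class.

    The majority class is down-sampled uniformly at random without
    replacement to the minority count; the result is shuffled.  Fully
    deterministic for a given seed.
    """
    n0, n1 = segments.class_counts()
    if n0 == 0 or n1 == 0:
        raise ValueError(f"cannot balance: class counts are {n0} / {n1}")
    rng = np.random.default_rng(seed)
    idx0 = np.nonzero(segments.labels == 0)[0]
    idx1 = np.nonzero(segments.labels == 1)[0]
    m = min(n0, n1)
    keep0 = rng.choice(idx0, size=m, replace=False) if n0 > m else idx0
    keep1 = rng.choice(idx1, size=m, replace=False) if n1 > m else idx1
    keep = np.concatenate([keep0, keep1])
    rng.shuffle(keep)
    return segments.subset(keep)


def reshape_for_model(segments: SegmentSet) -> np.ndarray:
    """Expose segments as single-plane 2-D images for the 2-D conv models.

    Returns an array of shape (n_segments, n_channels, segment_samples, 1):
    each segment is one height-by-width plane (electrodes x time) with one
    input channel.
    """
    return segments.tensor[..., None]
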