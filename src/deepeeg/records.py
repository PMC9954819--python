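"""In-memory containers for multichannel EEG recordings.

An :class:`EEGRecording` holds a ``channels x samples`` signal matrix in
microvolts together with its sampling rate and any seizure annotations.
Time is measured in seconds from record start; seizure intervals are
half-open, ``[onset_s, offset_s)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np


@dataclass(frozen=True, order=True)
class SeizureInterval:
    """A labeled ictal episode, in seconds from record start."""

    onset_s: float
    offset_s: float
    label: str = "ictal"

    def __post_init__(self):
        if not 0 <= self.onset_s < self.offset_s:
            raise ValueError(
                f"invalid seizure interval [{self.onset_s}, {self.offset_s}): "
                "need 0 <= onset < offset"
            )

    @property
    def duration_s(self) -> float:
        return self.offset_s - self.onset_s

    def overlaps(self, other: "SeizureInterval") -> bool:
        return self.onset_s < other.offset_s and other.onset_s < self.offset_s

    def contains(self, start_s: float, stop_s: float) -> bool:
        """True if [start_s, stop_s) lies entirely inside this interval."""
        return self.onset_s <= start_s and stop_s <= self.offset_s


@dataclass
class EEGRecording:
    """Multichannel EEG signal with sampling rate and seizure annotations.

    Parameters
    ----------
    signal : ndarray, shape (n_channels, n_samples)
        Scalp potentials in microvolts.
    fs : float
        Sampling rate in Hz.
    channel_names : list of str
        One name per channel.
    annotations : list of SeizureInterval
        Ictal episodes, kept sorted by onset.
    subject_id : str
        Free-form subject/record identifier.
    """

    signal: np.ndarray
    fs: float
    channel_names: list[str] = field(default_factory=list)
    annotations: list[SeizureInterval] = field(default_factory=list)
    subject_id: str = ""

    def __post_init__(self):
        self.signal = np.asarray(self.signal, dtype=np.float64)
        if self.signal.ndim != 2:
            raise ValueError("signal must be a 2-D channels x samples array")
        if self.signal.shape[0] < 1:
            raise ValueError("need at least one channel")
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if not self.channel_names:
            self.channel_names = [f"CH{i + 1}" for i in range(self.n_channels)]
        if len(self.channel_names) != self.n_channels:
            raise ValueError(
                f"{len(self.channel_names)} channel names for "
                f"{self.n_channels} channels"
            )
        for iv in self.annotations:
            if iv.offset_s > self.duration_s + 1e-9:
                raise ValueError(
                    f"annotation {iv} extends past record end "
                    f"({self.duration_s:.3f} s)"
                )
        self.annotations = sorted(self.annotations)

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def copy(self) -> "EEGRecording":
        return EEGRecording(
            signal=self.signal.copy(),
            fs=self.fs,
            channel_names=list(self.channel_names),
            annotations=list(self.annotations),
            subject_id=self.subject_id,
        )

    def with_annotation(self, interval: SeizureInterval) -> "EEGRecording":
        """Return a copy carrying one additional seizure interval.

        Raises ``ValueError`` if the new interval overlaps an existing one
        (labels must stay unambiguous) or falls outside the record.
        """
        if interval.offset_s > self.duration_s + 1e-9:
            raise ValueError(
                f"interval [{interval.onset_s}, {interval.offset_s}) outside "
                f"record of duration {self.duration_s:.3f} s"
            )
        for existing in self.annotations:
            if interval.overlaps(existing):
                raise ValueError(
                    f"interval [{interval.onset_s}, {interval.offset_s}) "
                    f"overlaps existing [{existing.onset_s}, {existing.offset_s})"
                )
        out = self.copy()
        out.annotations = sorted(out.annotations + [interval])
        return out


def _replace(rec: EEGRecording, **kw) -> EEGRecording:
    out = rec.copy()
    for k, v in kw.items():
        setattr(out, k, v)
    return out
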