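"""Synthetic multichannel EEG with seizures and artifacts.

The generator produces labeled recordings for exercising the full
detection pipeline without clinical data.  It makes no claim of
physiological realism; it is spectrally controllable and fully
deterministic under a seed.

* Interictal background: per-band filtered Gaussian noise (delta 0.5-4,
  theta 4-8, alpha 8-13, beta 13-30, gamma 30-45 Hz) generated as
  independent sources and mixed across channels by a random orthogonal
  matrix, plus a common sinusoidal alpha component.  Channels are therefore
  mutually correlated, as scalp EEG is.
* Ictal episodes: an amplitude-modulated spike-and-wave train (sharp
  Gaussian spike plus slow sinusoid per cycle, default 3 Hz) added on top
  of the background and annotated as a seizure interval.
* Artifacts: EMG (20-60 Hz band-limited noise), eye-blink transients
  (sparse sub-2-Hz bumps on frontal channels) and i.i.d. Gaussian white
  noise, each with its own amplitude control.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

from .errors import ConfigurationError
from .records import EEGRecording, SeizureInterval

__all__ = [
    "BANDS",
    "ArtifactConfig",
    "SynthSpec",
    "generate_background",
    "inject_ictal",
    "add_artifacts",
    "generate_labeled_dataset",
    "write_cohort",
]

#: Canonical EEG frequency bands, Hz.  Gamma is capped at 45 Hz here to
#: stay well below Nyquist at the 256-Hz default rate.
BANDS: dict[str, tuple[float, float]] = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
    "gamma": (30.0, 45.0),
}

#: Default relative band powers of the interictal background.  Chosen to
#: resemble a drowsy pediatric scalp EEG: delta/theta dominant, a clear
#: alpha rhythm, weak fast activity.
DEFAULT_BAND_POWERS: dict[str, float] = {
    "delta": 1.0,
    "theta": 0.7,
    "alpha": 0.8,
    "beta": 0.3,
    "gamma": 0.1,
}


@dataclass(frozen=True)
class ArtifactConfig:
    """Per-family artifact switches; an amplitude of 0 disables a family.

    Amplitudes are RMS in microvolts (for white noise, the SD).
    """

    emg_amplitude_uv: float = 0.0
    blink_amplitude_uv: float = 0.0
    white_noise_sigma_uv: float = 0.0
    blink_rate_hz: float = 0.25
    frontal_channels: tuple[int, ...] = (0, 1)

    @property
    def any_enabled(self) -> bool:
        return (
            self.emg_amplitude_uv > 0
            or self.blink_amplitude_uv > 0
            or self.white_noise_sigma_uv > 0
        )


@dataclass(frozen=True)
class SynthSpec:
    """Parameters of the synthetic EEG generator.

    ``ictal_rate_hz`` is the dominant spike-and-wave discharge frequency;
    ``ictal_amp_gain`` the multiplicative amplitude of the discharge
    relative to background RMS.  ``background_rms_uv`` sets the overall
    amplitude scale.
    """

    fs: float = 256.0
    n_channels: int = 23
    band_powers: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BAND_POWERS)
    )
    ictal_rate_hz: float = 3.0
    ictal_amp_gain: float = 5.0
    background_rms_uv: float = 30.0
    artifact_config: ArtifactConfig = field(default_factory=ArtifactConfig)
    seed: int = 0

    def __post_init__(self):
        if self.fs <= 0 or self.n_channels < 1:
            raise ConfigurationError("fs must be > 0 and n_channels >= 1")
        unknown = set(self.band_powers) - set(BANDS)
        if unknown:
            raise ConfigurationError(f"unknown bands {sorted(unknown)}")
        if any(v < 0 for v in self.band_powers.values()):
            raise ConfigurationError("band powers must be nonnegative")
        if not any(v > 0 for v in self.band_powers.values()):
            raise ConfigurationError("at least one band must have power > 0")
        if self.ictal_amp_gain <= 1:
            raise ConfigurationError("ictal_amp_gain must be > 1")
        f_max = max(
            BANDS[b][1] for b, p in self.band_powers.items() if p > 0
        )
        f_max = max(f_max, self.ictal_rate_hz)
        if self.fs <= 2 * f_max:
            raise ConfigurationError(
                f"fs = {self.fs} Hz violates Nyquist for highest synthesized "
                f"frequency {f_max} Hz"
            )


def _band_sources(spec: SynthSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    """Independent band-limited unit-variance sources, one set per channel."""
    k = spec.n_channels
    out = np.zeros((k, n))
    nyq = spec.fs / 2
    total = sum(spec.band_powers.values())
    for band, power in spec.band_powers.items():
        if power <= 0:
            continue
        lo, hi = BANDS[band]
        sos = sps.butter(4, [lo / nyq, hi / nyq], btype="bandpass", output="sos")
        white = rng.standard_normal((k, n))
        comp = sps.sosfiltfilt(sos, white, axis=1)
        sd = comp.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        comp /= sd
        out += math.sqrt(power / total) * comp
    return out


def generate_background(spec: SynthSpec, duration_s: float) -> EEGRecording:
    """Generate interictal background with the requested band powers.

    The per-channel power spectrum concentrates in the bands given nonzero
    power; channels are correlated through a random orthogonal mixing of
    shared band-limited sources.  Deterministic under ``spec.seed``.
    """
    if duration_s <= 0:
        raise ConfigurationError("duration_s must be positive")
    rng = np.random.default_rng(spec.seed)
    n = int(round(duration_s * spec.fs))
    sources = _band_sources(spec, n, rng)

    # random orthogonal mixing -> correlated channels, spectra preserved
    k = spec.n_channels
    if k > 1:
        q, _ = np.linalg.qr(rng.standard_normal((k, k)))
        mixed = q @ sources
    else:
        mixed = sources

    # common alpha rhythm (phase-locked across channels) if alpha is on
    alpha_power = spec.band_powers.get("alpha", 0.0)
    if alpha_power > 0:
        total = sum(spec.band_powers.values())
        t = np.arange(n) / spec.fs
        f0 = rng.uniform(9.5, 10.5)
        gains = rng.uniform(0.5, 1.0, size=k)
        sine = np.sin(2 * np.pi * f0 * t + rng.uniform(0, 2 * np.pi))
        mixed += (
            math.sqrt(alpha_power / total)
            * 0.5
            * gains[:, None]
            * sine[None, :]
        )

    mixed *= spec.background_rms_uv / mixed.std()
    return EEGRecording(
        signal=mixed,
        fs=spec.fs,
        channel_names=[f"SYN{i + 1:02d}" for i in range(k)],
        annotations=[],
        subject_id=f"synth-{spec.seed}",
    )


def _spike_wave(spec: SynthSpec, n: int, fs: float, rng: np.random.Generator):
    """Unit-scale spike-and-wave template of length n samples."""
    t = np.arange(n) / fs
    f = spec.ictal_rate_hz
    period = 1.0 / f
    wave = np.sin(2 * np.pi * f * t)  # slow wave, fundamental at f
    phase = np.mod(t, period)
    spike = 1.6 * np.exp(-0.5 * ((phase - 0.15 * period) / 0.02) ** 2)
    return wave + spike


def inject_ictal(
    rec: EEGRecording,
    onset_s: float,
    offset_s: float,
    spec: SynthSpec,
) -> EEGRecording:
    """Superimpose an annotated spike-and-wave discharge on a recording.

    The discharge RMS is ``spec.ictal_amp_gain`` times the background RMS
    outside the interval, tapered at the edges, with random per-channel
    gains.  Raises on zero-length, out-of-range or overlapping intervals.
    """
    if not 0 <= onset_s < offset_s:
        raise ValueError(
            f"invalid ictal interval [{onset_s}, {offset_s}): need onset < offset"
        )
    if offset_s > rec.duration_s + 1e-9:
        raise ValueError(
            f"interval [{onset_s}, {offset_s}) outside record of "
            f"{rec.duration_s:.3f} s"
        )
    interval = SeizureInterval(onset_s, offset_s)
    out = rec.with_annotation(interval)  # overlap/range checks live here

    i0 = int(round(onset_s * rec.fs))
    i1 = int(round(offset_s * rec.fs))
    n = i1 - i0
    rng = np.random.default_rng(
        np.random.SeedSequence([spec.seed, i0, i1, rec.n_samples])
    )
    template = _spike_wave(spec, n, rec.fs, rng)

    envelope = sps.windows.tukey(n, alpha=min(0.4, 2.0 / max(offset_s - onset_s, 1e-9)))
    template = template * envelope

    outside = np.ones(rec.n_samples, dtype=bool)
    outside[i0:i1] = False
    bg_rms = rec.signal[:, outside].std() if outside.any() else rec.signal.std()
    target_rms = spec.ictal_amp_gain * bg_rms
    t_rms = template.std()
    if t_rms > 0:
        template *= target_rms / t_rms

    gains = rng.uniform(0.75, 1.25, size=rec.n_channels)
    out.signal[:, i0:i1] += gains[:, None] * template[None, :]
    return out


def add_artifacts(
    rec: EEGRecording, config: ArtifactConfig, seed: int = 0
) -> EEGRecording:
    """Contaminate a recording with EMG, eye-blink and white-noise artifacts.

    Zero amplitudes are no-ops; with every family disabled the input is
    returned unchanged (as a copy).
    """
    out = rec.copy()
    rng = np.random.default_rng(np.random.SeedSequence([seed, rec.n_samples]))
    n = rec.n_samples
    nyq = rec.fs / 2

    if config.emg_amplitude_uv > 0:
        if nyq <= 60:
            raise ConfigurationError(
                f"EMG band 20-60 Hz needs fs > 120 Hz, got {rec.fs}"
            )
        sos = sps.butter(6, [20 / nyq, 60 / nyq], btype="bandpass", output="sos")
        emg = sps.sosfiltfilt(sos, rng.standard_normal((rec.n_channels, n)), axis=1)
        emg *= config.emg_amplitude_uv / emg.std()
        out.signal += emg

    if config.blink_amplitude_uv > 0:
        width = int(round(0.5 * rec.fs))  # 500-ms blink, energy < 2 Hz
        bump = sps.windows.hann(width)
        n_events = rng.poisson(config.blink_rate_hz * rec.duration_s)
        starts = rng.integers(0, max(1, n - width), size=n_events)
        blink = np.zeros(n)
        for s in starts:
            blink[s : s + width] += bump[: n - s]
        for ch in config.frontal_channels:
            if ch < rec.n_channels:
                out.signal[ch] += config.blink_amplitude_uv * blink

    if config.white_noise_sigma_uv > 0:
        out.signal += config.white_noise_sigma_uv * rng.standard_normal(
            (rec.n_channels, n)
        )

    return out


def generate_labeled_dataset(
    spec: SynthSpec,
    n_records: int,
    seizure_fraction: float,
    duration_s: float,
) -> list[EEGRecording]:
    """Generate a seeded cohort of recordings, a fraction with one seizure.

    Each seizure record carries exactly one annotated ictal interval with
    onset/offset on whole seconds (so fixed-length windows tile it
    cleanly).  Per-record RNG substreams are derived from ``spec.seed`` and
    the record index, so the cohort is reproducible independent of
    generation order.
    """
    if n_records <= 0:
        raise ConfigurationError("n_records must be positive")
    if not 0 <= seizure_fraction <= 1:
        raise ConfigurationError("seizure_fraction must be in [0, 1]")
    if duration_s < 8:
        raise ConfigurationError("records shorter than 8 s are not useful here")
    n_seizure = int(round(n_records * seizure_fraction))
    records = []
    for i in range(n_records):
        rec_spec = replace(spec, seed=int(np.random.default_rng(
            np.random.SeedSequence([spec.seed, i])
        ).integers(0, 2**31 - 1)))
        rec = generate_background(rec_spec, duration_s)
        rec.subject_id = f"synth-{spec.seed}-{i:03d}"
        if i < n_seizure:
            rng = np.random.default_rng(np.random.SeedSequence([spec.seed, i, 1]))
            dur = int(rng.integers(
                max(2, int(0.15 * duration_s)), max(3, int(0.3 * duration_s)) + 1
            ))
            onset = int(rng.integers(1, int(duration_s) - dur))
            rec = inject_ictal(rec, float(onset), float(onset + dur), rec_spec)
        if spec.artifact_config.any_enabled:
            rec = add_artifacts(rec, spec.artifact_config, seed=rec_spec.seed)
        records.append(rec)
    return records


def write_cohort(records: list[EEGRecording], out_dir) -> list[str]:
    """Write a cohort as EDF files plus one CHB-MIT-style summary file.

    Returns the EDF file names written.  The summary file is named
    ``summary.txt`` and uses the same dialect the annotation parser reads,
    so synthetic cohorts exercise the real ingestion path.
    """
    from pathlib import Path

    from .annotations import write_annotation_summary
    from .edf import write_edf

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    names, entries = [], []
    for i, rec in enumerate(records):
        name = f"synth_{i:03d}.edf"
        write_edf(rec, out_dir / name)
        names.append(name)
        entries.append((name, rec.annotations))
    write_annotation_summary(out_dir / "summary.txt", entries, fs=records[0].fs)
    return names
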