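"""Minimal EDF (European Data Format) reader and writer.

EDF stores polygraphic signals as 16-bit integers with a per-channel linear
mapping between digital and physical units.  This module supports the plain
EDF profile used by scalp-EEG corpora such as CHB-MIT: uniform sampling rate
across channels, contiguous records, no EDF+ annotation channels.

The writer quantizes to 16 bits over a configurable physical range
(default +/-1000 uV, a typical scalp-EEG dynamic range), so a write/read
round trip is exact up to the quantization step
``(phys_max - phys_min) / 2**16``.
"""

from __future__ import annotations

import datetime
import math
import os
from pathlib import Path

import numpy as np

from .errors import UnsupportedFormatError
from .records import EEGRecording

__all__ = ["read_edf", "write_edf", "quantization_step"]

_HDR_FIXED = 256  # bytes before the per-signal header block

DEFAULT_PHYSICAL_RANGE = (-1000.0, 1000.0)
_DIG_MIN, _DIG_MAX = -32768, 32767


def quantization_step(phys_min: float, phys_max: float) -> float:
    """Amplitude resolution of 16-bit EDF over a physical range."""
    return (phys_max - phys_min) / (_DIG_MAX - _DIG_MIN + 1)


def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii", errors="replace")[:width]
    return b + b" " * (width - len(b))


def _num(value, width: int) -> bytes:
    s = f"{value}"
    if len(s) > width:
        # densest float representation that fits the fixed-width field
        for prec in range(width, 0, -1):
            s = f"{float(value):.{prec}g}"
            if len(s) <= width:
                break
    if len(s) > width:
        raise ValueError(f"value {value!r} does not fit in {width} ascii chars")
    return _pad(s, width)


def write_edf(
    rec: EEGRecording,
    path: str | os.PathLike,
    physical_range: tuple[float, float] = DEFAULT_PHYSICAL_RANGE,
) -> None:
    """Write a recording as a plain EDF file.

    Samples outside ``physical_range`` are clipped.  If the record length is
    a whole number of seconds, 1-second data records are used; otherwise the
    whole signal is stored as a single data record.
    """
    phys_min, phys_max = map(float, physical_range)
    if not phys_min < phys_max:
        raise ValueError("physical_range must be increasing")
    n_ch, n_samp = rec.signal.shape
    fs = rec.fs

    if abs(fs - round(fs)) < 1e-9 and n_samp % round(fs) == 0:
        spr = int(round(fs))                  # samples per (1 s) record
        n_records = n_samp // spr
        record_dur = 1
    else:
        spr = n_samp
        n_records = 1
        record_dur = n_samp / fs

    header_bytes = _HDR_FIXED + 256 * n_ch
    now = datetime.datetime(2000, 1, 1)
    parts = [
        _pad("0", 8),
        _pad(rec.subject_id or "X", 80),
        _pad("Startdate 01-JAN-2000", 80),
        _pad(now.strftime("%d.%m.%y"), 8),
        _pad(now.strftime("%H.%M.%S"), 8),
        _num(header_bytes, 8),
        _pad("", 44),
        _num(n_records, 8),
        _num(record_dur if record_dur != int(record_dur) else int(record_dur), 8),
        _num(n_ch, 4),
    ]
    # per-signal header fields, each field for all signals consecutively
    parts.append(b"".join(_pad(name, 16) for name in rec.channel_names))
    parts.append(b"".join(_pad("", 80) for _ in range(n_ch)))      # transducer
    parts.append(b"".join(_pad("uV", 8) for _ in range(n_ch)))
    parts.append(b"".join(_num(phys_min, 8) for _ in range(n_ch)))
    parts.append(b"".join(_num(phys_max, 8) for _ in range(n_ch)))
    parts.append(b"".join(_num(_DIG_MIN, 8) for _ in range(n_ch)))
    parts.append(b"".join(_num(_DIG_MAX, 8) for _ in range(n_ch)))
    parts.append(b"".join(_pad("", 80) for _ in range(n_ch)))      # prefilter
    parts.append(b"".join(_num(spr, 8) for _ in range(n_ch)))
    parts.append(b"".join(_pad("", 32) for _ in range(n_ch)))

    scale = (_DIG_MAX - _DIG_MIN) / (phys_max - phys_min)
    clipped = np.clip(rec.signal, phys_min, phys_max)
    digital = np.rint((clipped - phys_min) * scale + _DIG_MIN).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(b"".join(parts))
        # records: for each record, each signal's samples consecutively
        for r in range(n_records):
            chunk = digital[:, r * spr : (r + 1) * spr]
            fh.write(np.ascontiguousarray(chunk).tobytes())


def _read_field(buf: bytes, offset: int, width: int) -> str:
    return buf[offset : offset + width].decode("ascii", errors="replace").strip()


def read_edf(path: str | os.PathLike) -> EEGRecording:
    """Read a plain EDF file into an :class:`EEGRecording`.

    The annotation list of the returned recording is empty; seizure
    annotations live in sidecar summary files (see
    :func:`deepeeg.annotations.parse_annotation_summary`).

    Raises
    ------
    UnsupportedFormatError
        If channels have different sampling rates, or the header is not
        valid EDF.
    OSError
        If the file cannot be read.
    """
    path = Path(path)
    with open(path, "rb") as fh:
        fixed = fh.read(_HDR_FIXED)
        if len(fixed) < _HDR_FIXED:
            raise UnsupportedFormatError(f"{path}: truncated EDF header")
        try:
            header_bytes = int(_read_field(fixed, 184, 8))
            n_records = int(_read_field(fixed, 236, 8))
            record_dur = float(_read_field(fixed, 244, 8))
            n_ch = int(_read_field(fixed, 252, 4))
        except ValueError as exc:
            raise UnsupportedFormatError(f"{path}: malformed EDF header") from exc
        if n_ch < 1:
            raise UnsupportedFormatError(f"{path}: no signals declared")
        subject = _read_field(fixed, 8, 80)

        sig_hdr = fh.read(header_bytes - _HDR_FIXED)
        if len(sig_hdr) < 256 * n_ch:
            raise UnsupportedFormatError(f"{path}: truncated signal header")

        def fields(offset, width):
            base = offset * n_ch
            return [
                _read_field(sig_hdr, base + i * width, width) for i in range(n_ch)
            ]

        labels = fields(0, 16)
        phys_min = np.array([float(v) for v in fields(16 + 80 + 8, 8)])
        phys_max = np.array([float(v) for v in fields(16 + 80 + 8 + 8, 8)])
        dig_min = np.array([float(v) for v in fields(16 + 80 + 8 + 16, 8)])
        dig_max = np.array([float(v) for v in fields(16 + 80 + 8 + 24, 8)])
        spr = [int(v) for v in fields(16 + 80 + 8 + 32 + 80, 8)]

        if len(set(spr)) != 1:
            raise UnsupportedFormatError(
                f"{path}: channels have mixed sampling rates "
                f"(samples per record {sorted(set(spr))})"
            )
        spr0 = spr[0]
        if record_dur <= 0:
            raise UnsupportedFormatError(f"{path}: non-positive record duration")
        fs = spr0 / record_dur

        n_total = n_records * n_ch * spr0
        raw = np.frombuffer(fh.read(n_total * 2), dtype="<i2")
        if raw.size < n_total:
            raise UnsupportedFormatError(f"{path}: data shorter than header declares")
        data = raw.reshape(n_records, n_ch, spr0)

    gain = (phys_max - phys_min) / (dig_max - dig_min)
    signal = np.concatenate(list(data), axis=1).astype(np.float64)
    signal = signal * gain[:, None] + (phys_min - dig_min * gain)[:, None]
    return EEGRecording(
        signal=signal,
        fs=fs,
        channel_names=labels,
        annotations=[],
        subject_id=subject,
    )
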