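"""Persistence of segment datasets.

A :class:`~deepeeg.preprocess.SegmentSet` is stored as a NumPy ``.npz``
archive with a self-describing JSON header carrying a format name and
version, so stale or foreign files are rejected with a clear error instead
of silently mis-loading.
"""

from __future__ import annotations

import json
import os
import zipfile

import numpy as np

from .errors import IncompatibleDatasetError
from .preprocess import NormalizationParams, SegmentSet

__all__ = ["save_dataset", "load_dataset", "FORMAT_NAME", "FORMAT_VERSION"]

FORMAT_NAME = "deepeeg-segmentset"
FORMAT_VERSION = 1


def save_dataset(segments: SegmentSet, path: str | os.PathLike) -> None:
    """Write a SegmentSet losslessly to ``path`` (.npz container)."""
    header = {
        "format": FORMAT_NAME,
        "version": FORMAT_VERSION,
        "fs": segments.fs,
        "segment_length_s": segments.segment_length_s,
        "meta": segments.meta,
        "normalized": segments.normalization is not None,
    }
    arrays = {
        "header": np.frombuffer(json.dumps(header).encode("utf-8"), dtype=np.uint8),
        "tensor": segments.tensor,
        "labels": segments.labels,
    }
    if segments.normalization is not None:
        p = segments.normalization
        arrays["norm_mu"] = p.mu
        arrays["norm_sigma"] = p.sigma
        arrays["norm_range"] = np.array([p.global_min, p.global_max])
    np.savez(path, **arrays)


def load_dataset(path: str | os.PathLike) -> SegmentSet:
    """Load a SegmentSet written by :func:`save_dataset`.

    Raises
    ------
    IncompatibleDatasetError
        On truncated files, foreign archives, or a version this package
        does not understand.
    """
    try:
        with np.load(path, allow_pickle=False) as data:
            if "header" not in data:
                raise IncompatibleDatasetError(
                    f"{path}: not a {FORMAT_NAME} container (no header)"
                )
            header = json.loads(bytes(data["header"]).decode("utf-8"))
            if header.get("format") != FORMAT_NAME:
                raise IncompatibleDatasetError(
                    f"{path}: container format {header.get('format')!r}, "
                    f"expected {FORMAT_NAME!r}"
                )
            if header.get("version") != FORMAT_VERSION:
                raise IncompatibleDatasetError(
                    f"{path}: container version {header.get('version')}, "
                    f"this package reads version {FORMAT_VERSION}"
                )
            norm = None
            if header.get("normalized"):
                lo, hi = data["norm_range"]
                norm = NormalizationParams(
                    mu=data["norm_mu"],
                    sigma=data["norm_sigma"],
                    global_min=float(lo),
                    global_max=float(hi),
                )
            return SegmentSet(
                tensor=data["tensor"],
                labels=data["labels"],
                fs=header["fs"],
                segment_length_s=header["segment_length_s"],
                normalization=norm,
                meta=header.get("meta", {}),
            )
    except (zipfile.BadZipFile, OSError, EOFError, ValueError, KeyError) as exc:
        raise IncompatibleDatasetError(
            f"{path}: unreadable or truncated dataset container ({exc})"
        ) from exc
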