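"""CHB-MIT-style seizure annotation summaries.

The CHB-MIT corpus ships one plain-text ``*-summary.txt`` per subject with
blocks like::

    File Name: chb01_03.edf
    Number of Seizures in File: 1
    Seizure 1 Start Time: 2996 seconds
    Seizure 1 End Time: 3036 seconds

(The seizure index is omitted in single-seizure files of some subjects;
both dialects are accepted.)  Times are seconds from the start of the named
EDF file; intervals are half-open ``[start, end)``.
"""

from __future__ import annotations

import os
import re

from .errors import AnnotationParseError
from .records import SeizureInterval

__all__ = ["parse_annotation_summary", "write_annotation_summary"]

_FILE_RE = re.compile(r"^File Name:\s*(\S+)", re.I)
_START_RE = re.compile(r"^Seizure(?:\s+\d+)?\s+Start Time:\s*([0-9.]+)\s*seconds", re.I)
_END_RE = re.compile(r"^Seizure(?:\s+\d+)?\s+End Time:\s*([0-9.]+)\s*seconds", re.I)


def parse_annotation_summary(
    path: str | os.PathLike, file_name: str | None = None
) -> list[SeizureInterval]:
    """Parse a CHB-MIT summary file into seizure intervals.

    Parameters
    ----------
    path : path
        Summary text file.
    file_name : str, optional
        If given, only seizures declared for this EDF file name are
        returned; otherwise all seizures in the summary are pooled.

    Returns
    -------
    list of SeizureInterval, sorted by onset.

    Raises
    ------
    AnnotationParseError
        On a seizure end at or before its start, or an end without a start.
    """
    intervals: list[SeizureInterval] = []
    current_file = None
    pending_start: float | None = None

    with open(path, "r", encoding="utf-8", errors="replace") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            m = _FILE_RE.match(line)
            if m:
                current_file = m.group(1)
                pending_start = None
                continue
            m = _START_RE.match(line)
            if m:
                pending_start = float(m.group(1))
                continue
            m = _END_RE.match(line)
            if m:
                end = float(m.group(1))
                if pending_start is None:
                    raise AnnotationParseError(
                        f"{path}:{lineno}: seizure end without a preceding "
                        f"start (file block {current_file!r})"
                    )
                if end <= pending_start:
                    raise AnnotationParseError(
                        f"{path}:{lineno}: seizure end {end} s is not after "
                        f"start {pending_start} s (file block {current_file!r})"
                    )
                if file_name is None or current_file == file_name:
                    intervals.append(SeizureInterval(pending_start, end))
                pending_start = None

    return sorted(intervals)


def write_annotation_summary(
    path: str | os.PathLike,
    entries: list[tuple[str, list[SeizureInterval]]],
    fs: float = 256.0,
) -> None:
    """Write annotations in the CHB-MIT summary dialect.

    ``entries`` maps each EDF file name to its seizure intervals, in the
    order the files should appear.
    """
    lines = [f"Data Sampling Rate: {fs:g} Hz", ""]
    for name, ivs in entries:
        lines.append(f"File Name: {name}")
        lines.append(f"Number of Seizures in File: {len(ivs)}")
        for k, iv in enumerate(sorted(ivs), start=1):
            lines.append(f"Seizure {k} Start Time: {iv.onset_s:g} seconds")
            lines.append(f"Seizure {k} End Time: {iv.offset_s:g} seconds")
        lines.append("")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")
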