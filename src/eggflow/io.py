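"""Readers and writers for EGG sample-stream text files.

Two dialects:

* ``plain_delimited`` — one sample per row, no header; the sampling rate
  must be supplied by the caller.  Lossless at full float precision.
* ``opensignals_text`` — the '#'-prefixed header dialect produced by
  common biosignal acquisition front ends: a JSON metadata line carrying
  the sampling rate and resolution, an ``EndOfHeader`` sentinel, then
  whitespace-delimited data columns (sequence number first, sample value
  last by default, as the exact column layout varies by device).

Event markers travel in a ``<file>.markers.json`` sidecar so the sample
file stays single-purpose and tool-friendly.
"""

from __future__ import annotations

import json
import sys
from dataclasses import dataclass
from pathlib import Path
from typing import IO

import numpy as np

from .core import ConfigurationError, ParseError, RawRecording

__all__ = ["FileDialect", "PLAIN", "OPENSIGNALS", "read_recording", "write_recording"]


@dataclass(frozen=True)
class FileDialect:
    """How a sample-stream text file is laid out."""

    kind: str  # "plain_delimited" or "opensignals_text"
    delimiter: str | None = None  # None = any whitespace
    comment_char: str = "#"
    column_index: int = -1  # which column holds the samples

    def __post_init__(self) -> None:
        if self.kind not in {"plain_delimited", "opensignals_text"}:
            raise ConfigurationError(f"unknown dialect kind {self.kind!r}")


PLAIN = FileDialect("plain_delimited")
OPENSIGNALS = FileDialect("opensignals_text")


def _marker_path(path: Path) -> Path:
    return path.with_name(path.name + ".markers.json")


def _detect_dialect(first_line: str) -> FileDialect:
    return OPENSIGNALS if first_line.startswith("#") else PLAIN


def _parse_opensignals_header(lines: list[str]) -> dict:
    """Pull device metadata out of the '#' header; JSON line wins."""
    meta: dict = {}
    for line in lines:
        body = line.lstrip("#").strip()
        if body.startswith("{"):
            try:
                payload = json.loads(body)
            except json.JSONDecodeError:
                continue
            # Either {"device": {...}} or a device-keyed mapping.
            for value in ([payload] if "sampling rate" in payload else payload.values()):
                if isinstance(value, dict) and "sampling rate" in value:
                    meta.update(value)
    return meta


def read_recording(
    path: str | Path,
    dialect: FileDialect | None = None,
    fs_override: float | None = None,
) -> RawRecording:
    """Read a sample-stream text file into a :class:`RawRecording`.

    With ``dialect=None`` the format is auto-detected: a leading ``#``
    means ``opensignals_text``, anything else ``plain_delimited``.  For
    the plain dialect the sampling rate must come from ``fs_override``;
    for the header dialect it is read from the header JSON (an override
    still wins).  Markers are loaded from the sidecar JSON if present.

    Raises
    ------
    ConfigurationError
        If no sampling rate can be determined.
    ParseError
        On a non-numeric sample value, with the line number.
    """
    path = Path(path)
    text = sys.stdin.read() if str(path) == "-" else path.read_text()
    lines = text.splitlines()
    if not lines:
        raise ParseError(f"{path}: file is empty")
    if dialect is None:
        dialect = _detect_dialect(lines[0])

    header: list[str] = []
    data_start = 0
    if dialect.kind == "opensignals_text":
        for i, line in enumerate(lines):
            if not line.startswith(dialect.comment_char):
                data_start = i
                break
            header.append(line)
            if "EndOfHeader" in line:
                data_start = i + 1
                break
        else:
            data_start = len(lines)

    meta = _parse_opensignals_header(header) if header else {}
    fs = fs_override if fs_override is not None else meta.get("sampling rate")
    if fs is None:
        raise ConfigurationError(
            f"{path}: no sampling rate in header and no fs override given"
        )

    samples: list[float] = []
    for lineno, line in enumerate(lines[data_start:], start=data_start + 1):
        stripped = line.strip()
        if not stripped or stripped.startswith(dialect.comment_char):
            continue
        fields = stripped.split(dialect.delimiter)
        try:
            samples.append(float(fields[dialect.column_index]))
        except (ValueError, IndexError) as exc:
            raise ParseError(f"{path}:{lineno}: cannot parse sample from {line!r}") from exc
    if not samples:
        raise ParseError(f"{path}: no data rows found")

    markers: tuple[tuple[float, str], ...] = ()
    if str(path) != "-":
        sidecar = _marker_path(path)
        if sidecar.exists():
            raw = json.loads(sidecar.read_text())
            markers = tuple((float(m["t"]), str(m["label"])) for m in raw)
    label = str(meta.get("label", ["EGG"])[0]) if isinstance(meta.get("label"), list) else "EGG"
    return RawRecording(
        samples=np.asarray(samples), fs=float(fs), markers=markers, channel_label=label
    )


def write_recording(
    rec: RawRecording, path: str | Path, dialect: FileDialect | None = None
) -> None:
    """Write a recording as text; round-trips losslessly via ``%.17g``.

    ``plain_delimited`` emits one sample per row.  ``opensignals_text``
    emits the '#' header (JSON metadata with the sampling rate, then
    ``EndOfHeader``) followed by ``nSeq<TAB>value`` rows.  Markers, if
    any, go to the ``.markers.json`` sidecar.
    """
    dialect = dialect or PLAIN
    out: IO[str]
    to_stdout = str(path) == "-"
    out = sys.stdout if to_stdout else open(path, "w")
    try:
        if dialect.kind == "opensignals_text":
            meta = {
                "device": {
                    "sampling rate": rec.fs,
                    "resolution": [16],
                    "column": ["nSeq", rec.channel_label],
                    "label": [rec.channel_label],
                }
            }
            out.write("# EGG Text File Format\n")
            out.write("# " + json.dumps(meta["device"] | {"device": "egg"}) + "\n")
            out.write("# EndOfHeader\n")
            for i, v in enumerate(rec.samples):
                out.write(f"{i}\t{v:.17g}\n")
        else:
            for v in rec.samples:
                out.write(f"{v:.17g}\n")
    finally:
        if not to_stdout:
            out.close()
    if not to_stdout and rec.markers:
        payload = [{"t": t, "label": lab} for t, lab in rec.markers]
        _marker_path(Path(path)).write_text(json.dumps(payload, indent=1))
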