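"""Reading, validating, and windowing the wearable device's text log.

One log line per received sample: a microsecond-precision timestamp, the
video frame index at reception time, gyroscope x/y/z, accelerometer
x/y/z (raw chip units in [-1000, 1000]), and a wrap-around sequence
number in [0, 255] used to detect transmission loss. Only the
accelerometer channels are consumed downstream; timestamps, frame
indices and gyro values are carried opaquely so a parsed stream can be
re-emitted byte-for-byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

ACCEL_MIN = -1000
ACCEL_MAX = 1000
SEQ_MOD = 256

#: Default analysis window: 160 samples (~4 s at 40 Hz).
WINDOW = 160
#: Default hop between consecutive windows: 40 samples (~1 s), i.e. 75% overlap.
STRIDE = 40


class LogParseError(ValueError):
    """A line could not be parsed into a sensor record."""


class LogValidationError(ValueError):
    """A parsed value violates the sensor's documented range."""


@dataclass(frozen=True)
class SensorRecord:
    """One received sample.

    ``timestamp`` is kept as an opaque string: windowing is by sample
    count, never wall time, so no datetime parsing is needed or wanted.
    """

    timestamp: str
    frame_index: int
    gyro: tuple[int, int, int]
    accel: tuple[int, int, int]
    seq: int

    def __post_init__(self) -> None:
        for v in self.accel:
            if not ACCEL_MIN <= v <= ACCEL_MAX:
                raise LogValidationError(
                    f"accelerometer value {v} outside [{ACCEL_MIN}, {ACCEL_MAX}]"
                )
        if not 0 <= self.seq < SEQ_MOD:
            raise LogValidationError(f"sequence number {self.seq} outside [0, 255]")


@dataclass
class SensorStream:
    """An ordered run of records from one recording."""

    records: list[SensorRecord] = field(default_factory=list)
    nominal_rate: float = 40.0

    def __len__(self) -> int:
        return len(self.records)

    def accel_array(self) -> np.ndarray:
        """Accelerometer samples as a float (n, 3) array."""
        if not self.records:
            return np.empty((0, 3), dtype=float)
        return np.array([r.accel for r in self.records], dtype=float)


@dataclass(frozen=True)
class Segment:
    """A 160x3 window of accelerometer samples.

    ``start_index`` is the 0-based offset of the first sample in the
    source stream; the window covers [start_index, start_index + n).
    """

    samples: np.ndarray  # (window, 3)
    start_index: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))
        if self.samples.ndim != 2 or self.samples.shape[1] != 3:
            raise ValueError(f"segment must be (n, 3), got {self.samples.shape}")


def parse_log(lines: Iterable[str], delimiter: str | None = ",") -> SensorStream:
    """Parse text log lines into a :class:`SensorStream`.

    Fields per line: timestamp, frame#, gx, gy, gz, ax, ay, az, seq.
    ``delimiter=None`` splits on whitespace; otherwise the delimiter is
    used with surrounding whitespace tolerated. Blank lines are skipped.

    Raises :class:`LogParseError` naming the 1-based line number on a
    malformed line, :class:`LogValidationError` on out-of-range values.
    """
    records: list[SensorRecord] = []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line:
            continue
        parts = line.split(delimiter) if delimiter else line.split()
        parts = [p.strip() for p in parts]
        if len(parts) < 9:
            raise LogParseError(
                f"line {lineno}: expected >= 9 fields, got {len(parts)}"
            )
        try:
            frame = int(parts[1])
            gyro = tuple(int(p) for p in parts[2:5])
            accel = tuple(int(p) for p in parts[5:8])
            seq = int(parts[8])
        except ValueError as exc:
            raise LogParseError(f"line {lineno}: {exc}") from None
        try:
            records.append(
                SensorRecord(
                    timestamp=parts[0], frame_index=frame,
                    gyro=gyro, accel=accel, seq=seq,
                )
            )
        except LogValidationError as exc:
            raise LogValidationError(f"line {lineno}: {exc}") from None
    return SensorStream(records=records)


def write_log(stream: SensorStream, delimiter: str = ",") -> list[str]:
    """Render a stream back to log lines; inverse of :func:`parse_log`."""
    lines = []
    for r in stream.records:
        fields = [r.timestamp, str(r.frame_index),
                  *map(str, r.gyro), *map(str, r.accel), str(r.seq)]
        lines.append(delimiter.join(fields))
    return lines


def check_sequence_continuity(stream: SensorStream) -> list[tuple[int, int]]:
    """Detect dropped samples from the wrap-around sequence counter.

    Returns ``(position, missing_count)`` pairs: a gap sits between
    records ``position`` and ``position + 1`` whenever the counter does
    not advance by exactly 1 modulo 256. An empty list means no loss.
    """
    gaps: list[tuple[int, int]] = []
    seqs = [r.seq for r in stream.records]
    for i in range(len(seqs) - 1):
        step = (seqs[i + 1] - seqs[i]) % SEQ_MOD
        if step != 1:
            gaps.append((i, (step - 1) % SEQ_MOD))
    return gaps


def segment_stream(
    stream: SensorStream | np.ndarray,
    window: int = WINDOW,
    stride: int = STRIDE,
) -> list[Segment]:
    """Cut the stream into overlapping fixed-length windows.

    Segment k starts at ``k * stride``; with the defaults consecutive
    segments share ``window - stride = 120`` samples (75% overlap).
    Accepts either a stream or a raw (n, 3) array.
    """
    if window < 1:
        raise ValueError(f"window must be >= 1, got {window}")
    if not 1 <= stride <= window:
        raise ValueError(f"stride must be in [1, window], got {stride}")
    data = stream.accel_array() if isinstance(stream, SensorStream) else np.asarray(stream, dtype=float)
    n = data.shape[0]
    if n < window:
        return []
    count = (n - window) // stride + 1
    return [Segment(samples=data[k * stride : k * stride + window], start_index=k * stride)
            for k in range(count)]


def segments_to_csv(segments: Sequence[Segment]) -> str:
    """Export segments as CSV (segment_id, sample_idx, x, y, z)."""
    out = ["segment_id,sample_idx,x,y,z"]
    for sid, seg in enumerate(segments):
        for i, (x, y, z) in enumerate(seg.samples):
            out.append(f"{sid},{i},{x:g},{y:g},{z:g}")
    return "\n".join(out) + "\n"
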