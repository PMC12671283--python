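"""Data model, validation, windowing and file I/O for wearable sensor streams.

A stream bundles five channels sampled at heterogeneous nominal rates:
triaxial accelerometer (m/s^2) and gyroscope (rad/s), plus scalar heart
rate (bpm), skin temperature (deg C) and humidity (%RH).  Time is seconds
from stream start; absolute wall-clock time is deliberately not modelled.

Two interchangeable on-disk formats are supported:

* CSV with header ``t,channel,v1,v2,v3`` (``v2``/``v3`` empty for scalar
  channels), UTF-8, ``.`` decimal separator;
* NDJSON, one ``{"t": ..., "channel": ..., "values": [...]}`` object per
  line.  NDJSON written by :func:`write_stream` round-trips bit-identically
  through :func:`read_stream`.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

from .errors import StreamParseError, StreamValidationError

#: channel name -> number of value components
CHANNELS: dict[str, int] = {
    "accel": 3,
    "gyro": 3,
    "heart_rate": 1,
    "temperature": 1,
    "humidity": 1,
}

VITAL_CHANNELS = ("heart_rate", "temperature", "humidity")

#: default nominal sampling rates, Hz
DEFAULT_RATES: dict[str, float] = {
    "accel": 50.0,
    "gyro": 50.0,
    "heart_rate": 1.0,
    "temperature": 0.2,
    "humidity": 0.2,
}


@dataclass(frozen=True)
class SensorSample:
    """One time-stamped reading on one channel.

    ``values`` has 3 components for accel/gyro, 1 for scalar channels.
    """

    t: float
    channel: str
    values: tuple[float, ...]

    def __post_init__(self):
        if self.channel not in CHANNELS:
            raise StreamValidationError(f"unknown channel {self.channel!r}")
        want = CHANNELS[self.channel]
        if len(self.values) != want:
            raise StreamValidationError(
                f"channel {self.channel!r} expects {want} value(s), "
                f"got {len(self.values)}"
            )
        if self.t < 0 or not math.isfinite(self.t):
            raise StreamValidationError(f"non-finite or negative t={self.t}")


@dataclass
class SensorStream:
    """Per-channel ordered sample arrays with nominal rates.

    ``times[ch]`` is a float array of timestamps (seconds), ``values[ch]``
    a ``(n, dim)`` float array of readings.
    """

    times: dict[str, np.ndarray] = field(default_factory=dict)
    values: dict[str, np.ndarray] = field(default_factory=dict)
    rates: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_RATES))
    subject: str = "anonymous"

    @property
    def channels(self) -> list[str]:
        return [ch for ch in CHANNELS if ch in self.times]

    def n_samples(self, channel: str | None = None) -> int:
        if channel is not None:
            return len(self.times.get(channel, ()))
        return sum(len(t) for t in self.times.values())

    def duration(self) -> float:
        """Largest timestamp over all channels (0.0 for an empty stream)."""
        maxima = [t[-1] for t in self.times.values() if len(t)]
        return float(max(maxima)) if maxima else 0.0

    def iter_samples(self, channel: str) -> Iterator[SensorSample]:
        for t, v in zip(self.times[channel], self.values[channel]):
            yield SensorSample(float(t), channel, tuple(float(x) for x in v))

    def __eq__(self, other) -> bool:  # value equality for round-trip tests
        if not isinstance(other, SensorStream):
            return NotImplemented
        if set(self.times) != set(other.times) or self.subject != other.subject:
            return False
        return all(
            np.array_equal(self.times[ch], other.times[ch])
            and np.array_equal(self.values[ch], other.values[ch])
            for ch in self.times
        )

    @classmethod
    def from_samples(
        cls,
        samples: Iterable[SensorSample],
        rates: dict[str, float] | None = None,
        subject: str = "anonymous",
    ) -> "SensorStream":
        buckets: dict[str, list[SensorSample]] = {}
        for s in samples:
            buckets.setdefault(s.channel, []).append(s)
        times = {}
        values = {}
        for ch, ss in buckets.items():
            times[ch] = np.array([s.t for s in ss], dtype=float)
            values[ch] = np.array([s.values for s in ss], dtype=float)
        stream = cls(times, values, dict(rates or DEFAULT_RATES), subject)
        report = validate_stream(stream)
        errors = [r for r in report if r.severity == "error"]
        if errors:
            raise StreamValidationError("; ".join(r.message for r in errors))
        return stream


@dataclass(frozen=True)
class SensorWindow:
    """Half-open time slice ``[start, end)`` of a stream."""

    start: float
    end: float
    times: dict[str, np.ndarray]
    values: dict[str, np.ndarray]

    def n_samples(self, channel: str) -> int:
        return len(self.times.get(channel, ()))


@dataclass(frozen=True)
class ButtonEvent:
    t: float
    kind: str  # "press" | "release"


@dataclass
class ButtonTrace:
    """Alternating press/release events, strictly increasing in time."""

    events: list[ButtonEvent] = field(default_factory=list)

    def __post_init__(self):
        prev_t = -math.inf
        for i, ev in enumerate(self.events):
            if ev.kind not in ("press", "release"):
                raise StreamValidationError(f"event {i}: bad kind {ev.kind!r}")
            if ev.t <= prev_t:
                raise StreamValidationError(
                    f"event {i}: non-increasing t={ev.t}"
                )
            expected = "press" if i % 2 == 0 else "release"
            if ev.kind != expected:
                raise StreamValidationError(
                    f"event {i}: expected {expected}, got {ev.kind}"
                )
            prev_t = ev.t


@dataclass
class TokenStream:
    """Time-stamped lower-cased word tokens from a transcriber."""

    times: np.ndarray = field(default_factory=lambda: np.empty(0))
    tokens: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        if len(self.times) != len(self.tokens):
            raise StreamValidationError("times/tokens length mismatch")
        if np.any(np.diff(self.times) < 0):
            raise StreamValidationError("token timestamps must be non-decreasing")
        for i, tok in enumerate(self.tokens):
            if not tok:
                raise StreamValidationError(f"token {i} is empty")
        self.tokens = [t.lower() for t in self.tokens]

    def __len__(self) -> int:
        return len(self.tokens)


@dataclass(frozen=True)
class ValidationIssue:
    severity: str  # "error" | "warning"
    channel: str | None
    t: float | None
    message: str


# ---------------------------------------------------------------------------
# file I/O


def read_stream(path: str | Path, dialect: str = "ndjson") -> SensorStream:
    """Read a sensor stream from CSV or NDJSON.

    Raises :class:`StreamParseError` naming the offending line for malformed
    rows and :class:`StreamValidationError` for decreasing timestamps.
    """
    path = Path(path)
    if dialect == "csv":
        samples = list(_read_csv(path))
    elif dialect == "ndjson":
        samples = list(_read_ndjson(path))
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return SensorStream.from_samples(samples)


def _read_csv(path: Path) -> Iterator[SensorSample]:
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            return
        if [h.strip() for h in header[:2]] != ["t", "channel"]:
            raise StreamParseError(f"bad header {header!r}", line=1)
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            try:
                t = float(row[0])
                channel = row[1].strip()
                vals = tuple(float(c) for c in row[2:5] if c.strip() != "")
            except (ValueError, IndexError) as exc:
                raise StreamParseError(str(exc), line=lineno) from exc
            try:
                yield SensorSample(t, channel, vals)
            except StreamValidationError as exc:
                raise StreamParseError(str(exc), line=lineno) from exc


def _read_ndjson(path: Path) -> Iterator[SensorSample]:
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
                t = float(obj["t"])
                channel = str(obj["channel"])
                vals = tuple(float(v) for v in obj["values"])
            except (json.JSONDecodeError, KeyError, TypeError, ValueError) as exc:
                raise StreamParseError(str(exc), line=lineno) from exc
            try:
                yield SensorSample(t, channel, vals)
            except StreamValidationError as exc:
                raise StreamParseError(str(exc), line=lineno) from exc


def write_stream(stream: SensorStream, path: str | Path, dialect: str = "ndjson") -> None:
    """Write a stream in canonical form (NDJSON round-trips bit-exactly).

    Samples are merged over channels in time order with a stable channel
    tie-break so output is deterministic.
    """
    path = Path(path)
    merged = _merged_samples(stream)
    if dialect == "ndjson":
        with path.open("w", encoding="utf-8") as fh:
            for s in merged:
                fh.write(
                    json.dumps(
                        {"t": s.t, "channel": s.channel, "values": list(s.values)},
                        separators=(",", ":"),
                    )
                    + "\n"
                )
    elif dialect == "csv":
        with path.open("w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(["t", "channel", "v1", "v2", "v3"])
            for s in merged:
                row = [repr(s.t), s.channel] + [repr(v) for v in s.values]
                row += [""] * (5 - len(row))
                writer.writerow(row)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def _merged_samples(stream: SensorStream) -> list[SensorSample]:
    out: list[SensorSample] = []
    for ch in stream.channels:
        out.extend(stream.iter_samples(ch))
    out.sort(key=lambda s: (s.t, s.channel))
    return out


def write_tokens(tokens: TokenStream, path: str | Path) -> None:
    """Token stream as NDJSON of {"t": ..., "token": ...}."""
    with Path(path).open("w", encoding="utf-8") as fh:
        for t, tok in zip(tokens.times, tokens.tokens):
            fh.write(json.dumps({"t": float(t), "token": tok},
                                separators=(",", ":")) + "\n")


def read_tokens(path: str | Path) -> TokenStream:
    times: list[float] = []
    toks: list[str] = []
    with Path(path).open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
                times.append(float(obj["t"]))
                toks.append(str(obj["token"]))
            except (json.JSONDecodeError, KeyError, TypeError, ValueError) as exc:
                raise StreamParseError(str(exc), line=lineno) from exc
    return TokenStream(times=np.asarray(times, dtype=float), tokens=toks)


def write_button_trace(trace: ButtonTrace, path: str | Path) -> None:
    """Button trace as NDJSON of {"t": ..., "kind": "press"|"release"}."""
    with Path(path).open("w", encoding="utf-8") as fh:
        for ev in trace.events:
            fh.write(json.dumps({"t": ev.t, "kind": ev.kind},
                                separators=(",", ":")) + "\n")


def read_button_trace(path: str | Path) -> ButtonTrace:
    events: list[ButtonEvent] = []
    with Path(path).open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
                events.append(ButtonEvent(float(obj["t"]), str(obj["kind"])))
            except (json.JSONDecodeError, KeyError, TypeError, ValueError) as exc:
                raise StreamParseError(str(exc), line=lineno) from exc
    return ButtonTrace(events=events)


# ---------------------------------------------------------------------------
# validation


def validate_stream(stream: SensorStream) -> list[ValidationIssue]:
    """Check every stream invariant; returns a report (never raises).

    One entry per violation, carrying channel and timestamp.  A declared
    nominal rate more than 20% away from the median observed rate yields a
    warning, not an error.
    """
    report: list[ValidationIssue] = []
    for ch in stream.times:
        if ch not in CHANNELS:
            report.append(ValidationIssue("error", ch, None, f"unknown channel {ch!r}"))
            continue
        t = stream.times[ch]
        v = stream.values[ch]
        if v.ndim != 2 or v.shape[1] != CHANNELS[ch]:
            report.append(
                ValidationIssue(
                    "error", ch, None,
                    f"{ch}: expected {CHANNELS[ch]} components, got shape {v.shape}",
                )
            )
            continue
        bad = np.flatnonzero(np.diff(t) < 0)
        if bad.size:
            i = int(bad[0]) + 1
            report.append(
                ValidationIssue(
                    "error", ch, float(t[i]),
                    f"{ch}: decreasing timestamp at index {i} (t={t[i]})",
                )
            )
        if np.any(t < 0):
            i = int(np.flatnonzero(t < 0)[0])
            report.append(
                ValidationIssue("error", ch, float(t[i]), f"{ch}: negative t at index {i}")
            )
        if not np.all(np.isfinite(v)):
            report.append(ValidationIssue("error", ch, None, f"{ch}: non-finite values"))
            continue
        if ch == "heart_rate":
            for i in np.flatnonzero(v[:, 0] <= 0):
                report.append(
                    ValidationIssue(
                        "error", ch, float(t[i]), f"heart_rate {v[i, 0]} not > 0"
                    )
                )
        if ch == "humidity":
            for i in np.flatnonzero((v[:, 0] < 0) | (v[:, 0] > 100)):
                report.append(
                    ValidationIssue(
                        "error", ch, float(t[i]),
                        f"humidity {v[i, 0]} outside [0, 100]",
                    )
                )
        declared = stream.rates.get(ch)
        if declared and len(t) > 3:
            dt = np.diff(t)
            med = float(np.median(dt))
            if med > 0:
                observed = 1.0 / med
                if abs(observed - declared) > 0.2 * declared:
                    report.append(
                        ValidationIssue(
                            "warning", ch, None,
                            f"{ch}: declared rate {declared} Hz vs observed "
                            f"~{observed:.3g} Hz",
                        )
                    )
    return report


# ---------------------------------------------------------------------------
# windowing


def window_stream(
    stream: SensorStream, window_s: float, hop_s: float
) -> list[SensorWindow]:
    """Slice a stream into half-open windows ``[start, start + window_s)``.

    Window starts are ``0, hop_s, 2*hop_s, ...`` up to and including the
    last hop multiple that is <= the stream's final timestamp, so every
    sample lands in at least one window.  A sample exactly at a window's
    end time belongs to the next window.
    """
    if window_s <= 0:
        raise ValueError(f"window_s must be > 0, got {window_s}")
    if not (0 < hop_s <= window_s):
        raise ValueError(f"hop_s must satisfy 0 < hop_s <= window_s, got {hop_s}")
    T = stream.duration()
    if stream.n_samples() == 0:
        return []
    n_windows = int(math.floor(T / hop_s)) + 1
    # presliced index bounds per channel via searchsorted (times are sorted)
    windows: list[SensorWindow] = []
    for i in range(n_windows):
        start = i * hop_s
        end = start + window_s
        times: dict[str, np.ndarray] = {}
        values: dict[str, np.ndarray] = {}
        for ch in stream.channels:
            t = stream.times[ch]
            lo = int(np.searchsorted(t, start, side="left"))
            hi = int(np.searchsorted(t, end, side="left"))
            times[ch] = t[lo:hi]
            values[ch] = stream.values[ch][lo:hi]
        windows.append(SensorWindow(start, end, times, values))
    return windows
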