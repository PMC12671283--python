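"""Vocal-tic channel: repetition detection and cue-phrase spotting.

Vocal tics show up as the same word blurted repeatedly over a short span.
This channel therefore watches a transcribed token stream (speech-to-text
is a pluggable external interface; see :class:`Transcriber`) and counts,
for every sliding 10-second window, how often the single most frequent
token occurs.  A window is flagged when that count exceeds the wearer's
calibration baseline by ``z`` standard deviations (default 3) — "more
repetition than is normal for this user" — with a hard floor of two
occurrences, since a word said once is not a repetition.  Flagged windows
raise alerts independently of the movement/vitals fusion, through the same
suppression state.

Two auxiliary pieces:

* an emergency cue phrase (default "notify tsband"): one spoken occurrence,
  tokens in order with bounded inter-token gaps, triggers an alert
  immediately.  The phrase is a config value so it can be changed if the
  wearer ever develops a verbal tic for it.
* a zero-phase 4th-order Butterworth high-pass (default cutoff 100 Hz) for
  raw waveforms, attenuating rumble and DC before transcription.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Protocol, Sequence

import numpy as np
from scipy import signal

from .errors import NotFittedError
from .sensor_model import TokenStream

REPETITION_HOP_S = 1.0


@dataclass(frozen=True)
class AudioConfig:
    repetition_window_s: float = 10.0
    baseline_z: float = 3.0
    cue_phrase: tuple[str, ...] = ("notify", "tsband")
    max_cue_gap_s: float = 2.0
    highpass_cutoff_hz: float = 100.0

    def __post_init__(self):
        if self.repetition_window_s <= 0 or self.max_cue_gap_s <= 0:
            raise ValueError("window and gap must be > 0")
        if self.highpass_cutoff_hz <= 0:
            raise ValueError("cutoff must be > 0")
        if not self.cue_phrase:
            raise ValueError("cue phrase must be non-empty")
        object.__setattr__(
            self, "cue_phrase", tuple(t.lower() for t in self.cue_phrase)
        )


class Transcriber(Protocol):
    """External speech-to-text interface: waveform -> token stream."""

    def transcribe(self, waveform: np.ndarray, rate_hz: float) -> TokenStream: ...


def high_pass(
    waveform: np.ndarray, rate_hz: float, cutoff_hz: float = 100.0
) -> np.ndarray:
    """Zero-phase 4th-order Butterworth high-pass filter."""
    if rate_hz <= 2 * cutoff_hz:
        raise ValueError(
            f"sample rate {rate_hz} Hz must exceed twice the cutoff {cutoff_hz} Hz"
        )
    sos = signal.butter(4, cutoff_hz, btype="highpass", fs=rate_hz, output="sos")
    return signal.sosfiltfilt(sos, np.asarray(waveform, dtype=float))


def read_wav(path) -> tuple[np.ndarray, float]:
    """Load a mono PCM WAV as (float waveform in [-1, 1], rate Hz).

    Multi-channel files are mixed down by averaging.
    """
    from scipy.io import wavfile

    rate, data = wavfile.read(path)
    data = np.asarray(data)
    if data.ndim > 1:
        data = data.mean(axis=1)
    if np.issubdtype(data.dtype, np.integer):
        data = data / float(np.iinfo(data.dtype).max)
    return data.astype(float), float(rate)


def repetition_counts(
    tokens: TokenStream, window_s: float = 10.0, hop_s: float = REPETITION_HOP_S
) -> tuple[np.ndarray, np.ndarray]:
    """Max single-token count per sliding half-open window.

    Returns ``(window_starts, counts)``; windows start at 0 and advance by
    ``hop_s`` up to the last token's timestamp.  Empty stream -> no windows.
    """
    if len(tokens) == 0:
        return np.empty(0), np.empty(0, dtype=int)
    t = tokens.times
    n_windows = int(np.floor(t[-1] / hop_s)) + 1
    starts = np.arange(n_windows) * hop_s
    counts = np.zeros(n_windows, dtype=int)
    toks = np.asarray(tokens.tokens, dtype=object)
    for i, s in enumerate(starts):
        lo = int(np.searchsorted(t, s, side="left"))
        hi = int(np.searchsorted(t, s + window_s, side="left"))
        if hi > lo:
            _, c = np.unique(toks[lo:hi], return_counts=True)
            counts[i] = int(c.max())
    return starts, counts


@dataclass
class RepetitionBaseline:
    """Per-user distribution of ordinary window repetition counts."""

    mean: float
    sd: float

    def __post_init__(self):
        if self.mean < 0 or self.sd < 0:
            raise ValueError("baseline mean/sd must be >= 0")


def fit_repetition_baseline(
    calibration_tokens: TokenStream, config: AudioConfig = AudioConfig()
) -> RepetitionBaseline:
    """Estimate the wearer's normal repetition level from calibration
    speech; an empty calibration yields mean 0, sd 0 (everything >= 2
    repeats will then flag)."""
    _, counts = repetition_counts(calibration_tokens, config.repetition_window_s)
    if counts.size == 0:
        return RepetitionBaseline(0.0, 0.0)
    return RepetitionBaseline(float(np.mean(counts)), float(np.std(counts)))


def audio_attack_flag(
    counts: np.ndarray,
    baseline: RepetitionBaseline | None,
    z: float = 3.0,
) -> np.ndarray:
    """Boolean flag per window: count > mean + z*sd, and at least 2."""
    if baseline is None:
        raise NotFittedError("repetition baseline not fitted")
    counts = np.asarray(counts)
    return (counts > baseline.mean + z * baseline.sd) & (counts >= 2)


def cue_phrase_detect(
    tokens: TokenStream, config: AudioConfig = AudioConfig()
) -> list[float]:
    """Times at which the cue phrase completes.

    Matches the cue tokens in order (other tokens may intervene) with
    consecutive matched tokens no more than ``max_cue_gap_s`` apart;
    overlapping candidate matches collapse to the earliest completion.
    """
    phrase = config.cue_phrase
    out: list[float] = []
    pos = 0
    last_t = None
    for t, tok in zip(tokens.times, tokens.tokens):
        if pos > 0 and last_t is not None and t - last_t > config.max_cue_gap_s:
            pos = 0  # phrase timed out; restart matching
        if tok == phrase[pos]:
            pos += 1
            last_t = float(t)
            if pos == len(phrase):
                out.append(float(t))
                pos = 0
                last_t = None
        elif pos > 0 and tok == phrase[0]:
            pos = 1  # e.g. "notify notify tsband"
            last_t = float(t)
    return out


def audio_status(
    flag_times: Sequence[float], now: float, window_s: float = 10.0
) -> str:
    """"unstable" iff any window was flagged within the trailing window."""
    recent = [t for t in flag_times if now - window_s < t <= now]
    return "unstable" if recent else "stable"
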