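"""Sliding-window trend detection on vital signs.

Each vital channel (heart rate, skin temperature, humidity as a sweat
surrogate) keeps a rolling one-hour buffer of samples.  Every new sample
triggers an ordinary-least-squares refit of value against time over the
trailing *trend window* (default 5 minutes) of that buffer, and the
channel's binary probability P_Vital flips to 1 — and latches — when the
fitted slope magnitude reaches the threshold (default 4/3).

The slope is deliberately estimated over the recent trend window rather
than the full hour: it approximates the instantaneous rate of change at
the newest sample, which is the quantity the threshold is about.  A
regression over a whole hour of mostly-flat history would dilute a
several-minute ramp far below any sensible threshold (a 2 z/min rise
sustained for 5 minutes after 55 flat minutes fits a full-hour slope of
under 0.1 z/min).  The full one-hour buffer is still retained — it is
what a reset re-assesses before monitoring resumes.

Because a single slope threshold must apply across channels with
incommensurate native units (bpm, deg C, %RH), samples are z-scored
against a per-user calibration baseline and time is measured in minutes:
the threshold therefore reads "4/3 calibration standard deviations per
minute", uniformly for every vital.  The threshold test is inclusive
(>= 4/3 or <= -4/3) and configurable per channel.

Once latched, the channel stops analysing: new samples are still buffered
(so a later reset sees the true last hour) but no refit happens and
P_Vital stays 1 until an explicit reset — either the wearer confirming
the attack is over, or the controller's one-hour quiet timeout.  A reset
clears the latch and immediately refits over the retained buffer, so a
still-rising vital re-latches at once.

At least ``min_points`` samples (default 10) spanning at least
``min_span_minutes`` (default 5) must be in the buffer before any flag can
fire: a point count alone is no guard for fast channels (10 heart-rate
samples cover 10 s, over which the per-minute slope of ordinary
fluctuation is enormous), so both floors apply.
"""

from __future__ import annotations

import warnings
from collections import deque
from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateFitError, NotFittedError
from .sensor_model import VITAL_CHANNELS, SensorSample, SensorStream

SLOPE_THRESHOLD = 4.0 / 3.0   # z-units per minute, inclusive
LOOKBACK_MINUTES = 60.0
MIN_POINTS = 10
MIN_SPAN_MINUTES = 3.0
TREND_WINDOW_MINUTES = 5.0


@dataclass(frozen=True)
class TrendFit:
    """OLS line y = b0 + b1 * x over (t minutes, z-value) points."""

    b0: float        # intercept, z-units
    b1: float        # slope, z-units per minute
    n: int
    span_minutes: float


@dataclass
class VitalBaseline:
    """Per-vital calibration mean and standard deviation in native units."""

    means: dict[str, float] = field(default_factory=dict)
    sds: dict[str, float] = field(default_factory=dict)

    def zscore(self, channel: str, value: float) -> float:
        if channel not in self.means:
            raise NotFittedError(f"no baseline for channel {channel!r}")
        return (value - self.means[channel]) / self.sds[channel]


def fit_vital_baseline(calibration: SensorStream) -> VitalBaseline:
    """Estimate per-vital mean/sd from an attack-agnostic calibration
    stream.  A zero-variance channel gets sd 1 with a warning."""
    baseline = VitalBaseline()
    for ch in VITAL_CHANNELS:
        if ch not in calibration.times or calibration.n_samples(ch) == 0:
            continue
        v = calibration.values[ch][:, 0]
        mean = float(np.mean(v))
        sd = float(np.std(v))
        if sd <= 0:
            warnings.warn(f"zero-variance calibration for {ch}: sd set to 1", stacklevel=2)
            sd = 1.0
        baseline.means[ch] = mean
        baseline.sds[ch] = sd
    return baseline


def fit_linear_trend(points) -> TrendFit:
    """OLS fit of a (t, value) sequence; t in minutes."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2:
        raise DegenerateFitError(f"need >= 2 points, got shape {pts.shape}")
    t, y = pts[:, 0], pts[:, 1]
    if np.ptp(t) == 0:
        raise DegenerateFitError("all timestamps identical")
    # centred normal equations for numerical stability
    tc = t - t.mean()
    b1 = float(np.dot(tc, y - y.mean()) / np.dot(tc, tc))
    b0 = float(y.mean() - b1 * t.mean())
    return TrendFit(b0=b0, b1=b1, n=len(t), span_minutes=float(np.ptp(t)))


def trend_flag(fit: TrendFit, threshold: float = SLOPE_THRESHOLD) -> bool:
    """True iff |slope| passes the (inclusive) threshold."""
    return fit.b1 >= threshold or fit.b1 <= -threshold


@dataclass
class VitalTrendState:
    """Rolling buffer + latch for one vital channel."""

    channel: str
    threshold: float = SLOPE_THRESHOLD
    lookback_minutes: float = LOOKBACK_MINUTES
    min_points: int = MIN_POINTS
    min_span_minutes: float = MIN_SPAN_MINUTES
    trend_window_minutes: float = TREND_WINDOW_MINUTES
    buffer: deque = field(default_factory=deque)  # (t_minutes, z) pairs
    latched: bool = False
    latch_t: float | None = None   # seconds
    last_fit: TrendFit | None = None

    @property
    def p_vital(self) -> int:
        return 1 if self.latched else 0


def update_vital(
    state: VitalTrendState,
    baseline: VitalBaseline,
    sample: SensorSample,
    now: float,
) -> VitalTrendState:
    """Ingest one sample at time ``now`` (seconds).

    While latched the sample is buffered but not analysed.  Otherwise the
    buffer is trimmed to the lookback window, refit, and the latch set if
    the slope threshold fires.
    """
    if sample.channel != state.channel:
        raise ValueError(
            f"sample channel {sample.channel!r} != state channel {state.channel!r}"
        )
    t_min = sample.t / 60.0
    z = baseline.zscore(state.channel, sample.values[0])
    state.buffer.append((t_min, z))
    _evict(state, now / 60.0)
    if state.latched:
        return state
    _refit(state, now)
    return state


def _evict(state: VitalTrendState, now_min: float) -> None:
    while state.buffer and state.buffer[0][0] < now_min - state.lookback_minutes:
        state.buffer.popleft()


def _refit(state: VitalTrendState, now: float) -> None:
    pts = np.asarray(state.buffer)
    if len(pts) == 0:
        return
    recent = pts[pts[:, 0] >= pts[-1, 0] - state.trend_window_minutes]
    if len(recent) < max(2, state.min_points):
        return
    if np.ptp(recent[:, 0]) < max(state.min_span_minutes, np.finfo(float).tiny):
        return
    fit = fit_linear_trend(recent)
    state.last_fit = fit
    if trend_flag(fit, state.threshold):
        state.latched = True
        state.latch_t = now


def reset_vital(state: VitalTrendState, reason: str, now: float) -> VitalTrendState:
    """Clear the latch (wearer confirmation or quiet timeout) and refit
    once over the retained last-hour buffer; a persisting trend re-latches
    immediately."""
    if reason not in ("confirm", "timeout"):
        raise ValueError(f"unknown reset reason {reason!r}")
    if not state.latched:
        if reason == "confirm":
            warnings.warn(
                f"reset(confirm) on unlatched vital {state.channel!r}: no-op",
                stacklevel=2,
            )
        return state
    state.latched = False
    state.latch_t = None
    _evict(state, now / 60.0)
    _refit(state, now)
    return state
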