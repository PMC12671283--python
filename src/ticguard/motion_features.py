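"""Wrist-motion feature extraction for the outlier detector.

Each analysis window of accelerometer + gyroscope samples is summarised by
six magnitude features describing how fast and how violently the wrist is
moving: mean and peak gravity-removed acceleration magnitude, an integrated
speed proxy, mean and peak angular speed, and the mean absolute angular
acceleration.  Tic bursts raise all six relative to a per-user baseline,
which is what the downstream Local Outlier Factor model keys on.

Gravity is removed by subtracting the per-window mean acceleration
vector: over a ~1 s window the mean is dominated by the quasi-static
gravity component (tic bursts are oscillatory and near zero-mean), and
unlike a fixed (0, 0, 9.81) reference it adapts to device orientation on
the wrist.  The mean is also exactly rotation-equivariant, so all
magnitude features are invariant under a rigid re-orientation of the
device — a property the test suite checks to machine precision.

True linear velocity is unobservable from a single wrist IMU (integration
drifts without position fixes), so ``speed_proxy`` is the trapezoidal
integral of the gravity-removed acceleration magnitude over the window,
reset every window.  It has units of m/s, is zero for a stationary wrist,
and grows with sustained vigorous movement, which is all the detector needs.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, fields
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import InsufficientDataError
from .sensor_model import SensorStream, SensorWindow, window_stream

#: feature names in canonical column order (matrix columns, CSV columns)
FEATURE_NAMES = (
    "mean_accel_mag",
    "peak_accel_mag",
    "speed_proxy",
    "mean_angular_speed",
    "peak_angular_speed",
    "angular_accel",
)


@dataclass(frozen=True)
class MotionFeatureVector:
    """Per-window motion summary; all magnitudes are >= 0, peaks >= means."""

    mean_accel_mag: float      # m/s^2, gravity removed
    peak_accel_mag: float      # m/s^2
    speed_proxy: float         # m/s, per-window integrated accel magnitude
    mean_angular_speed: float  # rad/s
    peak_angular_speed: float  # rad/s
    angular_accel: float       # rad/s^2, mean |d|omega|/dt|
    t: float = 0.0             # window start, seconds

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in FEATURE_NAMES], dtype=float)


def vector_magnitude(v: Sequence[float]) -> float:
    """Euclidean norm of a 3-vector."""
    arr = np.asarray(v, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"non-finite components in {v!r}")
    return float(np.linalg.norm(arr))


def extract_features(window: SensorWindow) -> MotionFeatureVector:
    """Compute the six motion features for one window.

    Requires at least two accel and two gyro samples; raises
    :class:`InsufficientDataError` naming the short channel otherwise.
    """
    for ch in ("accel", "gyro"):
        if window.n_samples(ch) < 2:
            raise InsufficientDataError(
                f"window [{window.start}, {window.end}) has "
                f"{window.n_samples(ch)} {ch} sample(s), need >= 2"
            )
    at = window.times["accel"]
    av = window.values["accel"]
    if not (np.all(np.isfinite(av)) and np.all(np.isfinite(window.values["gyro"]))):
        raise ValueError("non-finite sensor values in window")

    residual = av - np.mean(av, axis=0)  # gravity removal
    accel_mag = np.linalg.norm(residual, axis=1)
    speed_proxy = float(np.trapezoid(accel_mag, at)) if len(at) > 1 else 0.0

    gt = window.times["gyro"]
    gv = window.values["gyro"]
    ang_speed = np.linalg.norm(gv, axis=1)
    dt = np.diff(gt)
    with np.errstate(divide="ignore", invalid="ignore"):
        dws = np.abs(np.diff(ang_speed)) / dt
    dws = dws[np.isfinite(dws)]
    angular_accel = float(np.mean(dws)) if dws.size else 0.0

    return MotionFeatureVector(
        mean_accel_mag=float(np.mean(accel_mag)),
        peak_accel_mag=float(np.max(accel_mag)),
        speed_proxy=speed_proxy,
        mean_angular_speed=float(np.mean(ang_speed)),
        peak_angular_speed=float(np.max(ang_speed)),
        angular_accel=angular_accel,
        t=window.start,
    )


def features_over_stream(
    stream: SensorStream, window_s: float = 1.0, hop_s: float = 1.0
) -> list[MotionFeatureVector]:
    """One feature vector per window, boundaries identical to
    :func:`~ticguard.sensor_model.window_stream`; extraction errors are
    re-raised with the window index attached."""
    out: list[MotionFeatureVector] = []
    for i, w in enumerate(window_stream(stream, window_s, hop_s)):
        try:
            out.append(extract_features(w))
        except (InsufficientDataError, ValueError) as exc:
            raise type(exc)(f"window {i}: {exc}") from exc
    return out


def feature_matrix(features: Sequence[MotionFeatureVector]) -> np.ndarray:
    """Stack feature vectors into an (n, 6) matrix in canonical order."""
    return np.array([f.as_array() for f in features], dtype=float).reshape(
        len(features), len(FEATURE_NAMES)
    )


def write_feature_table(
    features: Sequence[MotionFeatureVector], path: str | Path
) -> None:
    """CSV dump (t + six features per row) for offline inspection."""
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(("t",) + FEATURE_NAMES)
        for f in features:
            writer.writerow([repr(f.t)] + [repr(getattr(f, n)) for n in FEATURE_NAMES])
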