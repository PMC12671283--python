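"""Seeded synthetic wearable-data generator with ground-truth labels.

No public dataset of wrist-worn recordings of tic attacks exists, so the
detector is exercised against a simulator that produces exactly the
statistical structure the detection stack assumes:

* **baseline movement** — AR(1) noise per accelerometer/gyroscope axis
  (stationary sd configurable) plus a constant gravity vector, modelling
  low-level everyday wrist motion;
* **tic-attack bursts** — sinusoidal oscillation at 3-6 Hz with slowly
  drifting phase on every axis, amplitude expressed as a multiple of the
  baseline sd; repetitive, high-energy and spectrally distinct from
  baseline, as motor tics are;
* **exercise confounders** — the same construction at lower frequency, so
  the known failure mode (exercise resembling an attack) can be generated
  deliberately and measured rather than hidden;
* **vital-sign ramps** — heart rate, skin temperature and humidity follow
  their baseline mean plus AR(1) noise, with a linear ramp during each
  attack episode and exponential relaxation afterwards, matching the
  linear-trend assumption of the regression detector;
* **vocal stream** — background chatter tokens at a Poisson rate from a
  fixed vocabulary, with the wearer's tic token repeated quasi-periodically
  during attacks.

All randomness flows from one root seed through named per-channel child
seeds, so adding or regenerating one channel never perturbs another, and
identical configs produce bit-identical output.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.signal import lfilter

import yaml

from .errors import ConfigError
from .sensor_model import (
    DEFAULT_RATES,
    ButtonEvent,
    ButtonTrace,
    SensorStream,
    TokenStream,
)

TWO_DAYS_S = 172800.0

#: stable per-channel spawn keys for child seeds
_CHANNEL_KEYS = {
    "accel": 0,
    "gyro": 1,
    "heart_rate": 2,
    "temperature": 3,
    "humidity": 4,
    "tokens": 5,
}


@dataclass(frozen=True)
class TicEpisode:
    """One tic-attack interval and its movement/vital/vocal signature."""

    start_s: float
    duration_s: float
    burst_freq_hz: float = 5.0          # within the 3-6 Hz tremor-like band
    amplitude: float = 8.0              # x baseline accel sd
    hr_ramp_bpm_per_min: float = 6.0
    temp_ramp_c_per_min: float = 0.2
    humidity_ramp_pct_per_min: float = 5.0

    @property
    def end_s(self) -> float:
        return self.start_s + self.duration_s


@dataclass(frozen=True)
class ExerciseEpisode:
    """Periodic non-tic movement (the detector's known confounder)."""

    start_s: float
    duration_s: float
    freq_hz: float = 1.5
    amplitude: float = 4.0  # x baseline accel sd

    @property
    def end_s(self) -> float:
        return self.start_s + self.duration_s


@dataclass(frozen=True)
class VitalSpec:
    mean: float
    sd: float


#: background vocabulary for simulated transcribed chatter; deliberately
#: excludes the default cue phrase and tic token
DEFAULT_VOCABULARY = (
    "the", "and", "to", "of", "in", "is", "it", "you", "that", "was",
    "for", "on", "are", "with", "they", "this", "have", "from", "one", "had",
)


@dataclass(frozen=True)
class VocalConfig:
    """Transcribed-speech model.

    Background chatter is Poisson-arriving tokens drawn uniformly from the
    vocabulary, with a hard cap on how often the same token may recur
    within one repetition window: unconstrained i.i.d. sampling grossly
    overstates short-range word repetition relative to conversational
    speech, where saying one word many times in ten seconds is precisely
    the vocal-tic signature the detector looks for.  The tic token ignores
    the cap — it *is* the pathology.
    """

    vocabulary: tuple[str, ...] = DEFAULT_VOCABULARY[:6]
    background_rate_hz: float = 0.6
    max_background_repeats: int = 3     # per repetition window (10 s)
    repetition_window_s: float = 10.0
    tic_token: str = "stop"
    tic_repetition_rate_hz: float = 1.0


@dataclass(frozen=True)
class ScenarioConfig:
    """Full specification of one simulated recording."""

    duration_s: float = 900.0
    rates: dict = field(default_factory=lambda: dict(DEFAULT_RATES))
    ar_coeff: float = 0.8
    accel_noise_sd: float = 0.3    # m/s^2, stationary sd of baseline motion
    gyro_noise_sd: float = 0.15    # rad/s
    gravity: tuple[float, float, float] = (0.0, 0.0, 9.81)
    tic_episodes: tuple[TicEpisode, ...] = ()
    exercise_episodes: tuple[ExerciseEpisode, ...] = ()
    vocal: VocalConfig = field(default_factory=VocalConfig)
    vitals: dict = field(
        default_factory=lambda: {
            "heart_rate": VitalSpec(75.0, 3.0),
            "temperature": VitalSpec(36.6, 0.1),
            "humidity": VitalSpec(40.0, 2.0),
        }
    )
    vital_recovery_tau_s: float = 120.0
    seed: int = 0


@dataclass(frozen=True)
class Interval:
    start: float
    end: float
    kind: str  # tic_attack | exercise | baseline


@dataclass
class GroundTruth:
    """Labelled truth intervals; attack intervals mirror the config."""

    intervals: list[Interval] = field(default_factory=list)
    duration_s: float = 0.0

    @property
    def attacks(self) -> list[Interval]:
        return [iv for iv in self.intervals if iv.kind == "tic_attack"]


def validate_scenario(config: ScenarioConfig) -> None:
    """Raise :class:`ConfigError` listing every offending episode."""
    problems: list[str] = []
    for kind, episodes in (
        ("tic", config.tic_episodes),
        ("exercise", config.exercise_episodes),
    ):
        prev_end = -np.inf
        for i, ep in enumerate(sorted(episodes, key=lambda e: e.start_s)):
            if ep.duration_s <= 0:
                problems.append(f"{kind} episode {i}: non-positive duration")
            if ep.start_s < 0 or ep.end_s > config.duration_s:
                problems.append(
                    f"{kind} episode {i}: [{ep.start_s}, {ep.end_s}) outside "
                    f"[0, {config.duration_s})"
                )
            if ep.start_s < prev_end:
                problems.append(f"{kind} episode {i}: overlaps previous episode")
            prev_end = ep.end_s
            if isinstance(ep, TicEpisode):
                if not (3.0 <= ep.burst_freq_hz <= 6.0):
                    problems.append(
                        f"tic episode {i}: burst frequency {ep.burst_freq_hz} "
                        "outside [3, 6] Hz"
                    )
                if ep.amplitude <= 0:
                    problems.append(f"tic episode {i}: non-positive amplitude")
    for name, rate in config.rates.items():
        if rate <= 0:
            problems.append(f"rate for {name} must be > 0")
    if not (0 <= config.ar_coeff < 1):
        problems.append(f"ar_coeff {config.ar_coeff} outside [0, 1)")
    if problems:
        raise ConfigError("; ".join(problems))


def _rng(config: ScenarioConfig, channel: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(_CHANNEL_KEYS[channel],))
    )


def _ar1(rng: np.random.Generator, n: int, coeff: float, stationary_sd: float) -> np.ndarray:
    innov_sd = stationary_sd * np.sqrt(1.0 - coeff**2)
    e = rng.normal(0.0, innov_sd, n)
    return lfilter([1.0], [1.0, -coeff], e)


def _burst(
    rng: np.random.Generator, t: np.ndarray, freq: float, amp: float
) -> np.ndarray:
    """Sinusoid with slowly drifting phase (random-walk jitter)."""
    phase0 = rng.uniform(0, 2 * np.pi)
    jitter = np.cumsum(rng.normal(0.0, 0.05, len(t)))
    return amp * np.sin(2 * np.pi * freq * t + phase0 + jitter)


def _imu_channel(
    config: ScenarioConfig, channel: str, noise_sd: float, offset: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    rate = config.rates[channel]
    n = int(round(config.duration_s * rate))
    t = np.arange(n) / rate
    rng = _rng(config, channel)
    axes = np.column_stack([_ar1(rng, n, config.ar_coeff, noise_sd) for _ in range(3)])
    for ep in config.tic_episodes:
        mask = (t >= ep.start_s) & (t < ep.end_s)
        amp = ep.amplitude * noise_sd
        for ax in range(3):
            axes[mask, ax] += _burst(rng, t[mask], ep.burst_freq_hz, amp)
    for ep in config.exercise_episodes:
        mask = (t >= ep.start_s) & (t < ep.end_s)
        amp = ep.amplitude * noise_sd
        for ax in range(3):
            axes[mask, ax] += _burst(rng, t[mask], ep.freq_hz, amp)
    return t, axes + offset


def _vital_ramp(config: ScenarioConfig, channel: str, t: np.ndarray) -> np.ndarray:
    """Linear rise during each attack, exponential relaxation after it."""
    ramp_attr = {
        "heart_rate": "hr_ramp_bpm_per_min",
        "temperature": "temp_ramp_c_per_min",
        "humidity": "humidity_ramp_pct_per_min",
    }[channel]
    out = np.zeros_like(t)
    for ep in config.tic_episodes:
        rate_per_s = getattr(ep, ramp_attr) / 60.0
        rise = ep.duration_s * rate_per_s
        during = (t >= ep.start_s) & (t < ep.end_s)
        out[during] += (t[during] - ep.start_s) * rate_per_s
        after = t >= ep.end_s
        out[after] += rise * np.exp(-(t[after] - ep.end_s) / config.vital_recovery_tau_s)
    return out


def _vital_channel(config: ScenarioConfig, channel: str) -> tuple[np.ndarray, np.ndarray]:
    rate = config.rates[channel]
    n = int(round(config.duration_s * rate))
    t = np.arange(n) / rate
    spec: VitalSpec = config.vitals[channel]
    rng = _rng(config, channel)
    v = spec.mean + _ar1(rng, n, config.ar_coeff, spec.sd) + _vital_ramp(config, channel, t)
    if channel == "humidity":
        v = np.clip(v, 0.0, 100.0)
    if channel == "heart_rate":
        v = np.maximum(v, 1.0)
    return t, v.reshape(-1, 1)


def _token_stream(config: ScenarioConfig) -> TokenStream:
    rng = _rng(config, "tokens")
    vc = config.vocal
    times: list[float] = []
    tokens: list[str] = []
    # background chatter: Poisson arrivals over the whole recording,
    # resampling tokens that would exceed the per-window repetition cap
    t = rng.exponential(1.0 / vc.background_rate_hz) if vc.background_rate_hz > 0 else np.inf
    tail = 0  # index of the oldest token still inside the trailing window
    while t < config.duration_s:
        while tail < len(times) and times[tail] <= t - vc.repetition_window_s:
            tail += 1
        recent = tokens[tail:]
        candidates = [
            w for w in vc.vocabulary
            if recent.count(w) < vc.max_background_repeats
        ] or list(vc.vocabulary)
        times.append(float(t))
        tokens.append(str(rng.choice(candidates)))
        t += rng.exponential(1.0 / vc.background_rate_hz)
    # vocal tic: quasi-periodic repetition of the tic token during attacks
    for ep in config.tic_episodes:
        if vc.tic_repetition_rate_hz <= 0:
            continue
        tt = ep.start_s + rng.uniform(0, 1.0 / vc.tic_repetition_rate_hz)
        while tt < ep.end_s:
            times.append(float(tt))
            tokens.append(vc.tic_token)
            tt += rng.exponential(1.0 / vc.tic_repetition_rate_hz)
    order = np.argsort(times, kind="stable")
    return TokenStream(
        times=np.asarray(times, dtype=float)[order] if times else np.empty(0),
        tokens=[tokens[i] for i in order],
    )


def _ground_truth(config: ScenarioConfig) -> GroundTruth:
    marks: list[Interval] = [
        Interval(ep.start_s, ep.end_s, "tic_attack") for ep in config.tic_episodes
    ] + [Interval(ep.start_s, ep.end_s, "exercise") for ep in config.exercise_episodes]
    marks.sort(key=lambda iv: iv.start)
    intervals: list[Interval] = []
    cursor = 0.0
    for iv in marks:
        if iv.start > cursor:
            intervals.append(Interval(cursor, iv.start, "baseline"))
        intervals.append(iv)
        cursor = max(cursor, iv.end)
    if cursor < config.duration_s:
        intervals.append(Interval(cursor, config.duration_s, "baseline"))
    return GroundTruth(intervals=intervals, duration_s=config.duration_s)


def simulate(config: ScenarioConfig) -> tuple[SensorStream, TokenStream, GroundTruth]:
    """Generate one labelled recording; bit-identical for a fixed config."""
    validate_scenario(config)
    times: dict[str, np.ndarray] = {}
    values: dict[str, np.ndarray] = {}
    times["accel"], values["accel"] = _imu_channel(
        config, "accel", config.accel_noise_sd, np.asarray(config.gravity)
    )
    times["gyro"], values["gyro"] = _imu_channel(
        config, "gyro", config.gyro_noise_sd, np.zeros(3)
    )
    for ch in ("heart_rate", "temperature", "humidity"):
        times[ch], values[ch] = _vital_channel(config, ch)
    stream = SensorStream(times=times, values=values, rates=dict(config.rates))
    return stream, _token_stream(config), _ground_truth(config)


def simulate_calibration(
    config: ScenarioConfig,
    compress: float = 1.0,
    episodes: Sequence[TicEpisode] = (),
) -> tuple[SensorStream, TokenStream]:
    """Generate the two-day-equivalent attack-free calibration recording.

    ``compress`` shrinks the duration (compress=1 is the full 48 h of
    samples) without changing the per-window feature statistics, which are
    stationary.  ``episodes`` can inject attacks into calibration to check
    that downstream fitting tolerates them.
    """
    if compress < 1:
        raise ValueError(f"compress must be >= 1, got {compress}")
    cal_seed = int(np.random.SeedSequence([config.seed, 7]).generate_state(1)[0] % 2**31)
    cal = replace(
        config,
        duration_s=TWO_DAYS_S / compress,
        tic_episodes=tuple(episodes),
        exercise_episodes=(),
        seed=cal_seed,
    )
    stream, tokens, _ = simulate(cal)
    return stream, tokens


# ---------------------------------------------------------------------------
# button traces


@dataclass(frozen=True)
class HoldSpec:
    t: float
    hold_s: float


@dataclass(frozen=True)
class CancelSpec:
    t: float
    count: int = 3
    span_s: float = 0.9


def simulate_button_trace(specs: Sequence[HoldSpec | CancelSpec]) -> ButtonTrace:
    """Expand hold/rapid-press specifications into a press/release trace."""
    spans: list[tuple[float, float]] = []
    events: list[ButtonEvent] = []
    for spec in specs:
        if isinstance(spec, HoldSpec):
            start, end = spec.t, spec.t + spec.hold_s
            events.append(ButtonEvent(start, "press"))
            events.append(ButtonEvent(end, "release"))
        elif isinstance(spec, CancelSpec):
            gap = spec.span_s / max(spec.count - 1, 1)
            start, end = spec.t, spec.t + spec.span_s
            for i in range(spec.count):
                press_t = spec.t + i * gap
                events.append(ButtonEvent(press_t, "press"))
                events.append(ButtonEvent(press_t + min(0.3 * gap, 0.03), "release"))
        else:
            raise TypeError(f"unknown spec {spec!r}")
        for s, e in spans:
            if start < e and s < end:
                raise ConfigError(f"button spec at t={spec.t} overlaps another")
        spans.append((start, end))
    events.sort(key=lambda ev: ev.t)
    return ButtonTrace(events=events)


# ---------------------------------------------------------------------------
# config / ground-truth file round-trips


def scenario_to_yaml(config: ScenarioConfig, path: str | Path) -> None:
    doc = asdict(config)
    doc["vitals"] = {ch: asdict(v) for ch, v in config.vitals.items()}
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=True), encoding="utf-8")


def scenario_from_yaml(path: str | Path) -> ScenarioConfig:
    doc = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    doc["tic_episodes"] = tuple(TicEpisode(**e) for e in doc.get("tic_episodes", ()))
    doc["exercise_episodes"] = tuple(
        ExerciseEpisode(**e) for e in doc.get("exercise_episodes", ())
    )
    vocal = doc.get("vocal", {})
    vocal["vocabulary"] = tuple(vocal.get("vocabulary", DEFAULT_VOCABULARY))
    doc["vocal"] = VocalConfig(**vocal)
    doc["vitals"] = {ch: VitalSpec(**v) for ch, v in doc.get("vitals", {}).items()}
    doc["gravity"] = tuple(doc.get("gravity", (0.0, 0.0, 9.81)))
    return ScenarioConfig(**doc)


def ground_truth_to_json(truth: GroundTruth, path: str | Path) -> None:
    doc = {
        "duration_s": truth.duration_s,
        "intervals": [asdict(iv) for iv in truth.intervals],
    }
    Path(path).write_text(json.dumps(doc, indent=1), encoding="utf-8")


def ground_truth_from_json(path: str | Path) -> GroundTruth:
    doc = json.loads(Path(path).read_text(encoding="utf-8"))
    return GroundTruth(
        intervals=[Interval(**iv) for iv in doc["intervals"]],
        duration_s=float(doc["duration_s"]),
    )
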