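"""End-to-end wiring: calibration, replay, event log, and evaluation.

``calibrate`` fits the three per-user baselines from an attack-agnostic
calibration recording: the LOF movement model, the vital-sign z-score
baselines, and the vocal repetition baseline.  ``run_pipeline`` then
replays a recording through every detection channel on a single merged
clock (samples processed in time order with a stable channel tie-break)
and emits one unified NDJSON-able event log.  ``evaluate`` scores that log
against simulator ground truth as sensitivity, false alarms per 24 h and
detection latency.
"""

from __future__ import annotations

import json
import statistics
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from . import audio as audio_mod
from .audio import AudioConfig, RepetitionBaseline
from .errors import NotFittedError
from .fusion import (
    AlertConfig,
    ControllerState,
    Event,
    FusionWeights,
    apply_cancellations,
    audio_alert,
    button_machine,
    fuse,
    step_controller,
)
from .lof import (
    DEFAULT_BUFFER_LEN,
    DEFAULT_K,
    LOFModel,
    MovementProbabilityState,
    fit_lof,
    lof_from_doc,
    lof_scores,
    lof_to_doc,
)
from .motion_features import feature_matrix, features_over_stream
from .sensor_model import VITAL_CHANNELS, ButtonTrace, SensorSample, SensorStream, TokenStream
from .simulator import GroundTruth
from .vitals import (
    LOOKBACK_MINUTES,
    MIN_POINTS,
    SLOPE_THRESHOLD,
    VitalBaseline,
    VitalTrendState,
    fit_vital_baseline,
    update_vital,
)

_MODEL_SCHEMA = "ticguard.model/1"


@dataclass(frozen=True)
class PipelineConfig:
    """Bundle of every tunable the replay pipeline uses."""

    window_s: float = 1.0
    hop_s: float = 1.0
    buffer_len: int = DEFAULT_BUFFER_LEN
    k: int | None = None  # LOF neighbour count; None = default (20, clipped)
    vital_threshold: float = SLOPE_THRESHOLD
    lookback_minutes: float = LOOKBACK_MINUTES
    min_points: int = MIN_POINTS
    match_tolerance_s: float = 30.0
    alert: AlertConfig = field(default_factory=AlertConfig)
    weights: FusionWeights = field(default_factory=FusionWeights)
    audio: AudioConfig = field(default_factory=AudioConfig)


@dataclass
class CalibratedModel:
    """Everything the two-day calibration period produces."""

    lof: LOFModel
    vital_baseline: VitalBaseline
    repetition_baseline: RepetitionBaseline


def calibrate(
    calibration_stream: SensorStream,
    calibration_tokens: TokenStream,
    config: PipelineConfig = PipelineConfig(),
) -> CalibratedModel:
    """Fit all per-user baselines from the calibration recording."""
    feats = features_over_stream(calibration_stream, config.window_s, config.hop_s)
    return CalibratedModel(
        lof=fit_lof(feats, k=config.k),
        vital_baseline=fit_vital_baseline(calibration_stream),
        repetition_baseline=audio_mod.fit_repetition_baseline(
            calibration_tokens, config.audio
        ),
    )


def save_model(model: CalibratedModel, path: str | Path) -> None:
    doc = {
        "schema": _MODEL_SCHEMA,
        "lof": lof_to_doc(model.lof),
        "vital_baseline": {
            "means": model.vital_baseline.means,
            "sds": model.vital_baseline.sds,
        },
        "repetition_baseline": {
            "mean": model.repetition_baseline.mean,
            "sd": model.repetition_baseline.sd,
        },
    }
    Path(path).write_text(json.dumps(doc, indent=1), encoding="utf-8")


def load_model(path: str | Path) -> CalibratedModel:
    doc = json.loads(Path(path).read_text(encoding="utf-8"))
    if doc.get("schema") != _MODEL_SCHEMA:
        raise ValueError(f"unexpected schema tag {doc.get('schema')!r}")
    return CalibratedModel(
        lof=lof_from_doc(doc["lof"]),
        vital_baseline=VitalBaseline(
            means=dict(doc["vital_baseline"]["means"]),
            sds=dict(doc["vital_baseline"]["sds"]),
        ),
        repetition_baseline=RepetitionBaseline(**doc["repetition_baseline"]),
    )


def run_pipeline(
    stream: SensorStream,
    tokens: TokenStream,
    buttons: ButtonTrace | None,
    model: CalibratedModel,
    config: PipelineConfig = PipelineConfig(),
    confirm_times: Sequence[float] = (),
) -> list[Event]:
    """Replay a recording through every channel; return the event log.

    All inputs share one clock (seconds from recording start).  Per tick
    (one motion window) the fused probability is recomputed from the
    current movement buffer and vital latches and pushed through the
    controller; audio repetition flags and cue-phrase hits raise alerts
    through the same suppression state; button holds/cancels are merged in
    afterwards and cancellations resolved against the combined log.
    """
    if model.lof is None:
        raise NotFittedError("pipeline needs a fitted LOF model")

    feats = features_over_stream(stream, config.window_s, config.hop_s)
    scores = lof_scores(model.lof, feature_matrix(feats)) if feats else np.empty(0)
    flags = scores > model.lof.theta

    # audio channel: repetition flags + cue phrase occurrences
    starts, counts = audio_mod.repetition_counts(
        tokens, config.audio.repetition_window_s
    )
    rep_flags = audio_mod.audio_attack_flag(
        counts, model.repetition_baseline, config.audio.baseline_z
    )
    cue_times = audio_mod.cue_phrase_detect(tokens, config.audio)

    # merged action timeline; priority orders actions at equal timestamps:
    # vitals first, then audio, then the fused tick that consumes them
    actions: list[tuple[float, int, str, object]] = []
    for ch in VITAL_CHANNELS:
        if ch not in stream.times:
            continue
        for t, v in zip(stream.times[ch], stream.values[ch]):
            actions.append((float(t), 0, ch, float(v[0])))
    for s, flag in zip(starts, rep_flags):
        if flag:
            actions.append((float(s + config.audio.repetition_window_s), 1,
                            "audio_flag", None))
    for t in cue_times:
        actions.append((float(t), 1, "cue", None))
    for i, f in enumerate(feats):
        actions.append((float(f.t + config.window_s), 2, "tick", i))
    for t in confirm_times:
        actions.append((float(t), 3, "confirm", None))
    actions.sort(key=lambda a: (a[0], a[1]))

    vstates = {
        ch: VitalTrendState(
            channel=ch,
            threshold=config.vital_threshold,
            lookback_minutes=config.lookback_minutes,
            min_points=config.min_points,
        )
        for ch in VITAL_CHANNELS
        if ch in stream.times and ch in model.vital_baseline.means
    }
    controller = ControllerState(config=config.alert, vitals=list(vstates.values()))
    mp = MovementProbabilityState(buffer_len=config.buffer_len)

    log: list[Event] = []
    latch_state = {ch: False for ch in vstates}
    for t, _, kind, payload in actions:
        if kind in vstates:
            update_vital(
                vstates[kind],
                model.vital_baseline,
                SensorSample(t, kind, (payload,)),
                now=t,
            )
        elif kind == "audio_flag":
            log.extend(audio_alert(controller, t, detail="repetition"))
        elif kind == "cue":
            log.extend(audio_alert(controller, t, detail="cue_phrase"))
        elif kind == "tick":
            mp.flags.append(1 if flags[payload] else 0)
            p_total = fuse(
                mp.p_movement,
                vstates["heart_rate"].p_vital if "heart_rate" in vstates else 0.0,
                vstates["temperature"].p_vital if "temperature" in vstates else 0.0,
                vstates["humidity"].p_vital if "humidity" in vstates else 0.0,
                config.weights,
            )
            log.extend(step_controller(controller, p_total, t))
        elif kind == "confirm":
            log.extend(step_controller(controller, 0.0, t, user_action="confirm_over"))
        # snapshot vital latch transitions into the log
        for ch, st in vstates.items():
            if st.latched != latch_state[ch]:
                latch_state[ch] = st.latched
                b1 = st.last_fit.b1 if st.last_fit else float("nan")
                log.append(
                    Event(t, "vital_snapshot", "vitals",
                          detail=f"{ch} b1={b1:.4g} latched={st.latched}")
                )

    if buttons is not None:
        log.extend(button_machine(buttons, config.alert))
    return apply_cancellations(log)


# ---------------------------------------------------------------------------
# evaluation


@dataclass
class DetectionMetrics:
    sensitivity: float
    false_alarms_per_24h: float
    median_latency_s: float | None
    true_positives: int
    false_positives: int
    missed: int

    def as_dict(self) -> dict:
        return {
            "sensitivity": self.sensitivity,
            "false_alarms_per_24h": self.false_alarms_per_24h,
            "median_latency_s": self.median_latency_s,
            "true_positives": self.true_positives,
            "false_positives": self.false_positives,
            "missed": self.missed,
        }

    def as_table(self) -> str:
        rows = [
            ("sensitivity", f"{self.sensitivity:.3f}"),
            ("false alarms / 24 h", f"{self.false_alarms_per_24h:.3f}"),
            ("median latency [s]",
             "n/a" if self.median_latency_s is None else f"{self.median_latency_s:.1f}"),
            ("true positives", str(self.true_positives)),
            ("false positives", str(self.false_positives)),
            ("missed attacks", str(self.missed)),
        ]
        width = max(len(r[0]) for r in rows)
        return "\n".join(f"{name:<{width}}  {val}" for name, val in rows)


ALERT_TYPES = ("alert_sent", "manual_alert")


def evaluate(
    events: Sequence[Event],
    truth: GroundTruth,
    match_tolerance_s: float = 30.0,
) -> DetectionMetrics:
    """Match alert events to ground-truth attack intervals.

    An alert matches an attack if it falls inside the interval or within
    the tolerance after its start; each attack consumes at most one
    (earliest) alert, the rest are false positives.
    """
    if match_tolerance_s < 0:
        raise ValueError(f"tolerance must be >= 0, got {match_tolerance_s}")
    alerts = sorted(e.t for e in events if e.type in ALERT_TYPES)
    used = [False] * len(alerts)
    latencies: list[float] = []
    tp = 0
    attacks = sorted(truth.attacks, key=lambda iv: iv.start)
    for iv in attacks:
        hi = max(iv.end, iv.start + match_tolerance_s)
        for j, t in enumerate(alerts):
            if not used[j] and iv.start <= t <= hi:
                used[j] = True
                tp += 1
                latencies.append(t - iv.start)
                break
    fp = used.count(False)
    missed = len(attacks) - tp
    days = truth.duration_s / 86400.0 if truth.duration_s > 0 else float("nan")
    return DetectionMetrics(
        sensitivity=tp / len(attacks) if attacks else 1.0,
        false_alarms_per_24h=fp / days if days and not np.isnan(days) else 0.0,
        median_latency_s=statistics.median(latencies) if latencies else None,
        true_positives=tp,
        false_positives=fp,
        missed=missed,
    )


# ---------------------------------------------------------------------------
# event log I/O


def write_event_log(events: Sequence[Event], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for ev in events:
            fh.write(json.dumps(ev.as_dict(), separators=(",", ":")) + "\n")


def read_event_log(path: str | Path) -> list[Event]:
    out: list[Event] = []
    with Path(path).open(encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            obj = json.loads(line)
            out.append(
                Event(
                    t=float(obj["t"]),
                    type=str(obj["type"]),
                    source=str(obj["source"]),
                    p_total=obj.get("p_total"),
                    detail=obj.get("detail", ""),
                )
            )
    return out
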