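"""Probability fusion, alert thresholding and the alert state machines.

The fused tic-attack probability is a fixed convex combination of the four
channel probabilities,

    P_Total = 0.7 P_Movement + 0.1 P_HeartRate + 0.1 P_Temperature
              + 0.1 P_Humidity,

weighted toward movement because vital-sign excursions accompany attacks
less reliably than motor tics do.  An alert fires when P_Total strictly
exceeds the threshold (default 0.80); thresholds at or below 0.70 draw a
validation warning, since below that level movement alone could trigger an
alert.

The controller is a two-state machine (``no_issues`` / ``possible_attack``).
While in ``possible_attack`` every further alert — automatic, audio or
otherwise routed through it — is suppressed, so the caretaker receives one
notification per episode.  The state returns to ``no_issues`` when the
wearer confirms the attack is over (which also resets the vital latches),
or after a quiet hour with no threshold exceedance (which resets only the
still-latched vitals).  Every alert is accompanied by exactly one buzzer
event on the band.

The manual channel is a push button: held for the full hold duration
(default 5 s) it raises an alert at the instant the hold completes, so
releasing early aborts; pressed at least 3 times within 1 s it cancels the
most recent uncancelled alert, whatever its source.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable

from .errors import ConfigError
from .sensor_model import ButtonTrace
from .vitals import VitalTrendState, reset_vital

DAY_SECONDS = 86400.0


@dataclass(frozen=True)
class FusionWeights:
    """Convex weights over (movement, heart rate, temperature, humidity)."""

    w_movement: float = 0.7
    w_heart_rate: float = 0.1
    w_temperature: float = 0.1
    w_humidity: float = 0.1

    def __post_init__(self):
        ws = (self.w_movement, self.w_heart_rate, self.w_temperature, self.w_humidity)
        if any(w < 0 for w in ws):
            raise ConfigError(f"negative fusion weight in {ws}")
        if abs(sum(ws) - 1.0) > 1e-9:
            raise ConfigError(f"fusion weights must sum to 1, got {sum(ws)}")


@dataclass(frozen=True)
class AlertConfig:
    """Alerting thresholds and timings."""

    threshold: float = 0.80          # alert iff P_Total > threshold (strict)
    min_recommended_threshold: float = 0.70
    resume_timeout_s: float = 3600.0  # quiet period before auto-resume
    hold_duration_s: float = 5.0      # button hold-to-alert
    cancel_press_count: int = 3
    cancel_span_s: float = 1.0
    calibration_period_s: float = 2 * DAY_SECONDS

    def __post_init__(self):
        for name in ("resume_timeout_s", "hold_duration_s", "cancel_span_s"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0, got {getattr(self, name)}")
        if not (0 < self.threshold < 1):
            raise ConfigError(f"threshold must lie in (0, 1), got {self.threshold}")
        if self.cancel_press_count < 2:
            raise ConfigError("cancel_press_count must be >= 2")


def validate_config(config: AlertConfig) -> list[str]:
    """Non-fatal checks; structural errors are raised at construction."""
    out = []
    if config.threshold <= config.min_recommended_threshold:
        out.append(
            f"alert threshold {config.threshold} is <= "
            f"{config.min_recommended_threshold}: at or below this level the "
            "movement channel alone can trigger an alert, defeating the "
            "multimodal design"
        )
    return out


def fuse(
    p_movement: float,
    p_heart_rate: float,
    p_temperature: float,
    p_humidity: float,
    weights: FusionWeights = FusionWeights(),
) -> float:
    """Weighted fusion of the four channel probabilities into P_Total."""
    ps = (p_movement, p_heart_rate, p_temperature, p_humidity)
    for name, p in zip(("movement", "heart_rate", "temperature", "humidity"), ps):
        if not (0.0 <= p <= 1.0) or not math.isfinite(p):
            raise ValueError(f"p_{name}={p} outside [0, 1]")
    return (
        weights.w_movement * p_movement
        + weights.w_heart_rate * p_heart_rate
        + weights.w_temperature * p_temperature
        + weights.w_humidity * p_humidity
    )


def alert_decision(p_total: float, config: AlertConfig = AlertConfig()) -> bool:
    """True iff P_Total is strictly over the alert threshold."""
    if not (0.0 <= p_total <= 1.0):
        raise ValueError(f"p_total={p_total} outside [0, 1]")
    return p_total > config.threshold


@dataclass(frozen=True)
class Event:
    """One entry of the unified event log."""

    t: float
    type: str    # alert_sent | buzzer | cancelled | status_change | warning
    source: str  # movement|vitals|fused|audio|manual|controller
    p_total: float | None = None
    detail: str = ""

    def as_dict(self) -> dict:
        d = {"t": self.t, "type": self.type, "source": self.source}
        if self.p_total is not None:
            d["p_total"] = self.p_total
        if self.detail:
            d["detail"] = self.detail
        return d


STATUS_NO_ISSUES = "no_issues"
STATUS_POSSIBLE_ATTACK = "possible_attack"


@dataclass
class ControllerState:
    """Fused-probability alert state machine with push suppression."""

    config: AlertConfig = field(default_factory=AlertConfig)
    status: str = STATUS_NO_ISSUES
    last_exceed_t: float | None = None  # last instant P_Total > threshold
    now: float = -math.inf
    vitals: list[VitalTrendState] = field(default_factory=list)


def step_controller(
    state: ControllerState,
    p_total: float,
    now: float,
    user_action: str = "none",
    source: str = "fused",
) -> list[Event]:
    """Advance the controller by one observation; returns emitted events.

    Order within a step: quiet-hour timeout, wearer confirmation, then the
    alert decision — so an alert can fire in the same step that cleared
    ``possible_attack``, but never while the status still is
    ``possible_attack``.
    """
    if now < state.now:
        raise ValueError(f"time went backwards: {now} < {state.now}")
    state.now = now
    events: list[Event] = []

    if alert_decision(p_total, state.config):
        exceeding_now = True
    else:
        exceeding_now = False

    # (d) quiet-hour auto-resume
    if (
        state.status == STATUS_POSSIBLE_ATTACK
        and not exceeding_now
        and state.last_exceed_t is not None
        and now - state.last_exceed_t >= state.config.resume_timeout_s
    ):
        state.status = STATUS_NO_ISSUES
        for v in state.vitals:
            if v.latched:
                reset_vital(v, "timeout", now)
        events.append(Event(now, "status_change", "controller",
                            detail="timeout -> no_issues"))

    # (c) wearer confirms the attack is over
    if user_action == "confirm_over":
        if state.status == STATUS_POSSIBLE_ATTACK:
            state.status = STATUS_NO_ISSUES
            for v in state.vitals:
                if v.latched:
                    reset_vital(v, "confirm", now)
            events.append(Event(now, "status_change", "controller",
                                detail="confirm_over -> no_issues"))
        else:
            warnings.warn("confirm_over while status is no_issues: no-op", stacklevel=2)
            events.append(Event(now, "warning", "controller",
                                detail="confirm_over while no_issues"))

    if exceeding_now:
        state.last_exceed_t = now

    # (a)/(b) alert or suppress
    if exceeding_now and state.status == STATUS_NO_ISSUES:
        state.status = STATUS_POSSIBLE_ATTACK
        events.append(Event(now, "alert_sent", source, p_total=p_total))
        events.append(Event(now, "buzzer", source, p_total=p_total))
        events.append(Event(now, "status_change", "controller",
                            detail="-> possible_attack"))
    return events


def audio_alert(state: ControllerState, now: float, detail: str = "") -> list[Event]:
    """Route an audio-channel alert through the shared suppression state.

    The audio channel bypasses fusion entirely — it alerts on its own
    evidence — but respects the one-alert-per-episode suppression.
    """
    if now < state.now:
        raise ValueError(f"time went backwards: {now} < {state.now}")
    state.now = now
    state.last_exceed_t = now
    if state.status != STATUS_NO_ISSUES:
        return []
    state.status = STATUS_POSSIBLE_ATTACK
    return [
        Event(now, "alert_sent", "audio", detail=detail),
        Event(now, "buzzer", "audio", detail=detail),
        Event(now, "status_change", "controller", detail="-> possible_attack"),
    ]


def button_machine(trace: ButtonTrace, config: AlertConfig = AlertConfig()) -> list[Event]:
    """Turn a press/release trace into manual alerts and cancels.

    A press held for at least the hold duration emits ``manual_alert`` +
    ``buzzer`` at the hold-completion instant (press time + hold), not at
    release.  A run of at least ``cancel_press_count`` presses whose first
    and last fall within ``cancel_span_s`` emits one ``cancelled`` event;
    the presses it used are consumed.
    """
    events: list[Event] = []
    presses = [ev.t for ev in trace.events if ev.kind == "press"]
    releases = [ev.t for ev in trace.events if ev.kind == "release"]

    for i, press_t in enumerate(presses):
        release_t = releases[i] if i < len(releases) else math.inf
        if release_t - press_t >= config.hold_duration_s:
            t_alert = press_t + config.hold_duration_s
            events.append(Event(t_alert, "manual_alert", "manual"))
            events.append(Event(t_alert, "buzzer", "manual"))

    i = 0
    n = config.cancel_press_count
    while i + n <= len(presses):
        if presses[i + n - 1] - presses[i] <= config.cancel_span_s:
            events.append(Event(presses[i + n - 1], "cancelled", "manual",
                                detail=f"{n} presses in "
                                       f"{presses[i + n - 1] - presses[i]:.3g} s"))
            i += n  # consume the presses that formed this cancel
        else:
            i += 1

    events.sort(key=lambda e: (e.t, e.type))
    return events


def apply_cancellations(log: Iterable[Event]) -> list[Event]:
    """Resolve each ``cancelled`` event against the most recent prior
    uncancelled alert (automatic, audio or manual); dangling cancels are
    dropped with a warning event."""
    out: list[Event] = []
    open_alerts: list[int] = []  # indices into out
    for ev in sorted(log, key=lambda e: (e.t, e.type)):
        if ev.type in ("alert_sent", "manual_alert"):
            open_alerts.append(len(out))
            out.append(ev)
        elif ev.type == "cancelled":
            if open_alerts:
                target = out[open_alerts.pop()]
                out.append(
                    Event(ev.t, "cancelled", ev.source,
                          detail=f"cancels {target.type}@{target.t:g}")
                )
            else:
                out.append(Event(ev.t, "warning", "controller",
                                 detail="cancel with no prior alert"))
        else:
            out.append(ev)
    return out
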