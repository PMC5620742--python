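"""Closed-loop tactile stimulus scheduling and heart-rate alarm.

When snoring is detected the controller runs a fixed vibration schedule —
by default three 3 s bursts separated by 1 s gaps, 11 s end to end with 9 s
of actuator-on time.  The schedule aborts immediately if snoring stops
mid-run ("disappears spontaneously"), and re-arms once finished so a
recurring snore episode triggers it again.  Independently, a heart-rate
reading outside the normal [40, 120] bpm band raises a rapid-pulse alarm.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

Interval = tuple[float, float]  # half-open [start, end) seconds


@dataclass(frozen=True)
class StimulusConfig:
    burst_seconds: float = 3.0
    gap_seconds: float = 1.0
    n_bursts: int = 3
    intensity_level: int = 1  # patient-adjustable; metadata only here

    def __post_init__(self) -> None:
        if self.burst_seconds <= 0 or self.gap_seconds < 0 or self.n_bursts < 1:
            raise ValueError("invalid stimulus configuration")

    @property
    def span_seconds(self) -> float:
        return (self.n_bursts * self.burst_seconds
                + (self.n_bursts - 1) * self.gap_seconds)

    @property
    def on_seconds(self) -> float:
        return self.n_bursts * self.burst_seconds


@dataclass(frozen=True)
class HeartRateConfig:
    """Normal heart-rate band in bpm; the bounds themselves do not alert."""

    low_bpm: float = 40.0
    high_bpm: float = 120.0
    pulse_on_seconds: float = 0.5
    pulse_off_seconds: float = 0.5

    def __post_init__(self) -> None:
        if not (0 < self.low_bpm < self.high_bpm):
            raise ValueError("require 0 < low_bpm < high_bpm")


@dataclass(frozen=True)
class StimulusState:
    """Controller state: idle, mid-schedule (burst_i/gap_i), or done."""

    phase: str = "idle"
    phase_entry_time: float = 0.0
    schedule_start: float = 0.0
    actuator_on: bool = False
    last_time: float = field(default=float("-inf"))


class TimeRegressionError(ValueError):
    pass


def build_schedule(cfg: StimulusConfig = StimulusConfig(),
                   trigger_time: float = 0.0) -> list[Interval]:
    """Actuator-on intervals for a schedule triggered at ``trigger_time``.

    Defaults give [t, t+3), [t+4, t+7), [t+8, t+11).
    """
    period = cfg.burst_seconds + cfg.gap_seconds
    return [(trigger_time + i * period, trigger_time + i * period + cfg.burst_seconds)
            for i in range(cfg.n_bursts)]


def _phase_at(cfg: StimulusConfig, elapsed: float) -> tuple[str, bool]:
    """Phase name and actuator flag at ``elapsed`` seconds into a schedule."""
    period = cfg.burst_seconds + cfg.gap_seconds
    if elapsed >= cfg.span_seconds:
        return "done", False
    i = int(elapsed // period)
    within = elapsed - i * period
    if within < cfg.burst_seconds:
        return f"burst_{i}", True
    return f"gap_{i}", False


def step(state: StimulusState, t: float, snore_active: bool,
         cfg: StimulusConfig = StimulusConfig()) -> tuple[StimulusState, bool]:
    """Advance the controller to time ``t`` with the current snore flag.

    Rules: idle + snoring -> start the schedule at ``t``; mid-schedule and
    snoring gone -> abort immediately (actuator off at this very call);
    schedule elapsed -> done, and a still/again active snore re-triggers.
    ``t`` must be non-decreasing across calls.
    """
    if t < state.last_time:
        raise TimeRegressionError(
            f"time went backwards: {t} < {state.last_time}")
    if not snore_active:
        # mid-schedule abort and post-completion disarm both land in idle
        return replace(state, phase="idle", phase_entry_time=t,
                       actuator_on=False, last_time=t), False
    # snoring is active
    if state.phase in ("idle", "done"):
        # no refractory period: a completed schedule re-triggers straight away
        phase, on = _phase_at(cfg, 0.0)
        return StimulusState(phase=phase, phase_entry_time=t, schedule_start=t,
                             actuator_on=on, last_time=t), on
    phase, on = _phase_at(cfg, t - state.schedule_start)
    entry = state.phase_entry_time if phase == state.phase else t
    return replace(state, phase=phase, phase_entry_time=entry,
                   actuator_on=on, last_time=t), on


def hr_alert(hr: float, cfg: HeartRateConfig = HeartRateConfig()) -> bool:
    """True iff the heart rate is outside the normal band (bounds inclusive-normal)."""
    if hr < 0:
        raise ValueError(f"heart rate cannot be negative: {hr}")
    return hr < cfg.low_bpm or hr > cfg.high_bpm


def hr_pulse_on(time_since_alert_start: float,
                cfg: HeartRateConfig = HeartRateConfig()) -> bool:
    """Rapid-pulse pattern while the HR alarm holds: 0.5 s on / 0.5 s off by default."""
    period = cfg.pulse_on_seconds + cfg.pulse_off_seconds
    return (time_since_alert_start % period) < cfg.pulse_on_seconds


def simulate_alerts(snore_flags: list[tuple[float, bool]],
                    hr_readings: list[tuple[float, float]] | None = None,
                    cfg: StimulusConfig = StimulusConfig(),
                    hr_cfg: HeartRateConfig = HeartRateConfig()) -> list[dict]:
    """Replay a (time, snore_active) trace — plus optional (time, bpm)
    readings — through the controller, returning actuation rows of
    ``{time_s, actuator_on, cause}`` with cause in {snore, hr, none}."""
    hr_by_time = dict(hr_readings or [])
    state = StimulusState()
    rows = []
    hr_alert_start: float | None = None
    for t, active in snore_flags:
        state, on = step(state, t, active, cfg)
        cause = "snore" if on else "none"
        if t in hr_by_time:
            if hr_alert(hr_by_time[t], hr_cfg):
                if hr_alert_start is None:
                    hr_alert_start = t
                if hr_pulse_on(t - hr_alert_start, hr_cfg):
                    on, cause = True, ("snore" if cause == "snore" else "hr")
            else:
                hr_alert_start = None
        rows.append({"time_s": t, "actuator_on": bool(on), "cause": cause})
    return rows
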