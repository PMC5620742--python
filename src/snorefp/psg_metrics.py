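"""Respiratory event scoring and AHI-family indices.

Scoring rules (AASM-style, as used for obstructive sleep apnea):

* **Apnea** — oro-nasal airflow cut for at least 10 s.  "Cut" is
  operationalised as flow at or below 10% of a rolling-median local
  baseline (the common scoring convention; configurable).
* **Hypopnea** — airflow reduced by at least 50% for at least 10 s, with
  either a >= 3% SpO2 desaturation (measured against the pre-event 30 s
  median, allowing a 30 s lag past the event for the dip) or an arousal
  inside the event.
* **AHI** — (apneas + hypopneas) / hours of sleep.  Severity grades:
  AHI < 5 Normal, 5–15 Mild, 16–30 Moderate, > 30 Severe; fractional
  values between 15 and 16 grade Mild.  AHI >= 15 is flagged clinically
  important.

Stratified indices (supine AHI, REM AHI) divide the events scored in a
stratum by the hours spent in it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import median_filter

APNEA_FLOW_FRACTION = 0.10
HYPOPNEA_FLOW_FRACTION = 0.50
MIN_EVENT_SECONDS = 10.0
SPO2_DROP_PERCENT = 3.0
SPO2_BASELINE_SECONDS = 30.0
SPO2_LAG_SECONDS = 30.0
BASELINE_WINDOW_SECONDS = 120.0
CLINICAL_AHI = 15.0


class NonUniformTraceError(ValueError):
    pass


@dataclass(frozen=True)
class Trace:
    """Uniformly sampled channel: times in seconds, one value per time."""

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        values = np.asarray(self.values, dtype=float)
        if times.shape != values.shape or times.ndim != 1:
            raise ValueError("times and values must be equal-length 1-D arrays")
        if len(times) >= 2:
            steps = np.diff(times)
            if np.any(steps <= 0) or not np.allclose(steps, steps[0], rtol=1e-6):
                raise NonUniformTraceError("trace must be strictly increasing "
                                           "with a uniform step")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)

    @property
    def dt(self) -> float:
        if len(self.times) < 2:
            raise ValueError("trace too short to have a step")
        return float(self.times[1] - self.times[0])


@dataclass(frozen=True)
class RespiratoryEvent:
    kind: str  # "apnea" | "hypopnea"
    start: float
    duration: float
    context: dict = field(default_factory=dict)

    @property
    def end(self) -> float:
        return self.start + self.duration


@dataclass(frozen=True)
class AHIReport:
    ahi: float
    apnea_index: float
    hypopnea_index: float
    supine_ahi: float | None
    rem_ahi: float | None
    osas_degree: str
    clinically_important: bool
    n_apneas: int
    n_hypopneas: int


def _rolling_baseline(flow: Trace, baseline_window: float) -> np.ndarray:
    """Rolling-median flow baseline, robust to the events themselves."""
    size = max(3, int(round(baseline_window / flow.dt)) | 1)  # odd window
    return median_filter(np.abs(flow.values), size=size, mode="nearest")


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal True runs as half-open index ranges [i, j)."""
    if not mask.any():
        return []
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return list(zip(edges[::2], edges[1::2]))


def _check_uniform(trace: Trace, min_rate: float = 1.0) -> None:
    if len(trace.times) < 2:
        raise NonUniformTraceError("trace too short")
    if 1.0 / trace.dt < min_rate - 1e-9:
        raise NonUniformTraceError(
            f"sampling rate {1.0 / trace.dt:.3f} Hz below required {min_rate} Hz")


def detect_apneas(airflow: Trace,
                  baseline_window: float = BASELINE_WINDOW_SECONDS,
                  cut_fraction: float = APNEA_FLOW_FRACTION,
                  min_duration: float = MIN_EVENT_SECONDS) -> list[RespiratoryEvent]:
    """Score maximal >= 10 s flow cessations, one event per cessation."""
    _check_uniform(airflow)
    baseline = _rolling_baseline(airflow, baseline_window)
    mask = np.abs(airflow.values) <= cut_fraction * baseline
    dt = airflow.dt
    events = []
    for i, j in _runs(mask):
        duration = (j - i) * dt
        if duration >= min_duration:
            events.append(RespiratoryEvent(kind="apnea",
                                           start=float(airflow.times[i]),
                                           duration=float(duration)))
    return events


def _spo2_qualifies(spo2: Trace, start: float, end: float,
                    min_drop: float, baseline_s: float, lag_s: float) -> bool:
    t = spo2.times
    pre = spo2.values[(t >= start - baseline_s) & (t < start)]
    if pre.size == 0:
        return False
    window = spo2.values[(t >= start) & (t <= end + lag_s)]
    if window.size == 0:
        return False
    return float(np.median(pre) - window.min()) >= min_drop


def detect_hypopneas(airflow: Trace, spo2: Trace | None = None,
                     arousals: list[float] | None = None,
                     baseline_window: float = BASELINE_WINDOW_SECONDS,
                     reduction_fraction: float = HYPOPNEA_FLOW_FRACTION,
                     apnea_cut_fraction: float = APNEA_FLOW_FRACTION,
                     min_duration: float = MIN_EVENT_SECONDS,
                     min_spo2_drop: float = SPO2_DROP_PERCENT,
                     spo2_baseline: float = SPO2_BASELINE_SECONDS,
                     spo2_lag: float = SPO2_LAG_SECONDS) -> list[RespiratoryEvent]:
    """Score >= 10 s partial flow reductions backed by a desaturation or arousal.

    Samples at or below the apnea cut are excluded so cessations score as
    apneas, not additionally as hypopneas.
    """
    _check_uniform(airflow)
    if spo2 is not None:
        _check_uniform(spo2)
        if not (np.isclose(spo2.times[0], airflow.times[0])
                and np.isclose(spo2.times[-1], airflow.times[-1])):
            raise NonUniformTraceError("airflow and SpO2 traces are misaligned")
        if np.any(spo2.values < 0) or np.any(spo2.values > 100):
            raise ValueError("SpO2 must lie in [0, 100] percent")
    arousals = arousals or []
    baseline = _rolling_baseline(airflow, baseline_window)
    flow = np.abs(airflow.values)
    mask = (flow <= reduction_fraction * baseline) & (flow > apnea_cut_fraction * baseline)
    dt = airflow.dt
    events = []
    for i, j in _runs(mask):
        duration = (j - i) * dt
        if duration < min_duration:
            continue
        start, end = float(airflow.times[i]), float(airflow.times[i]) + duration
        desat = (spo2 is not None
                 and _spo2_qualifies(spo2, start, end, min_spo2_drop,
                                     spo2_baseline, spo2_lag))
        aroused = any(start <= a < end for a in arousals)
        if desat or aroused:
            events.append(RespiratoryEvent(kind="hypopnea", start=start,
                                           duration=float(duration)))
    return events


def annotate_context(events: list[RespiratoryEvent],
                     position: Trace | None = None,
                     stage: Trace | None = None,
                     supine_code: float = 1.0,
                     rem_code: float = 1.0) -> list[RespiratoryEvent]:
    """Tag each event with supine/REM context sampled at its start time."""
    out = []
    for ev in events:
        ctx = dict(ev.context)
        if position is not None:
            idx = int(np.searchsorted(position.times, ev.start, side="right")) - 1
            ctx["supine"] = bool(position.values[max(idx, 0)] == supine_code)
        if stage is not None:
            idx = int(np.searchsorted(stage.times, ev.start, side="right")) - 1
            ctx["rem"] = bool(stage.values[max(idx, 0)] == rem_code)
        out.append(RespiratoryEvent(kind=ev.kind, start=ev.start,
                                    duration=ev.duration, context=ctx))
    return out


def classify_osas(ahi: float) -> str:
    """Severity grade from AHI (events/hour): <5 Normal, 5–15 Mild,
    16–30 Moderate, >30 Severe; fractional 15–16 grades Mild."""
    if ahi < 0:
        raise ValueError(f"AHI cannot be negative: {ahi}")
    if ahi < 5:
        return "Normal"
    if ahi < 16:
        return "Mild"
    if ahi <= 30:
        return "Moderate"
    return "Severe"


def _stratum_hours(trace: Trace | None, code: float) -> float | None:
    if trace is None:
        return None
    return float(np.count_nonzero(trace.values == code) * trace.dt / 3600.0)


def compute_indices(events: list[RespiratoryEvent], sleep_hours: float,
                    position: Trace | None = None,
                    stage: Trace | None = None,
                    supine_code: float = 1.0,
                    rem_code: float = 1.0) -> AHIReport:
    """Events-per-hour indices, stratified by position/stage where provided."""
    if sleep_hours <= 0:
        raise ValueError("sleep_hours must be positive")
    apneas = [e for e in events if e.kind == "apnea"]
    hypopneas = [e for e in events if e.kind == "hypopnea"]
    ahi = len(events) / sleep_hours

    def stratified(flag: str, hours: float | None) -> float | None:
        if hours is None:
            return None
        n = sum(1 for e in events if e.context.get(flag))
        return n / hours if hours > 0 else 0.0

    supine_hours = _stratum_hours(position, supine_code)
    rem_hours = _stratum_hours(stage, rem_code)
    return AHIReport(
        ahi=ahi,
        apnea_index=len(apneas) / sleep_hours,
        hypopnea_index=len(hypopneas) / sleep_hours,
        supine_ahi=stratified("supine", supine_hours),
        rem_ahi=stratified("rem", rem_hours),
        osas_degree=classify_osas(ahi),
        clinically_important=ahi >= CLINICAL_AHI,
        n_apneas=len(apneas),
        n_hypopneas=len(hypopneas),
    )
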