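"""Synthetic audio and physiology for exercising the whole pipeline.

Snore clips model the acoustics of palatal/tongue-base snoring: a breathing-
paced train of harmonic bursts whose fundamental lies in the 200–1000 Hz
band (palate-level snores sit near 200 Hz, tongue-base snores near 1 kHz).
A clip is a *stereotyped* signature for one sleeper — burst timing and
spectrum are set by the parameters, while the seed varies only the breath
noise, per-burst loudness and partial phases.  That mirrors how a
fingerprint database is used in practice: templates are samples of the
wearer's own snore, and later clips from the same sleeper share their
time-frequency constellation.

Synthetic nights plant apnea/hypopnea events that satisfy the scoring
definitions exactly (>= 10 s cessation; >= 50% reduction with a >= 3%
desaturation or an arousal), with coupled SpO2 desaturations, heart-rate
dips/rebounds, position/stage annotations, and a snore-episode schedule
preceding events with a configurable coupling probability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from snorefp.audio_io import CANONICAL_RATE, AudioSignal, normalize_peak, resample
from snorefp.psg_metrics import RespiratoryEvent, Trace

SNORE_BAND_HZ = (200.0, 1000.0)
NONSNORE_KINDS = ("white_noise", "chirp", "tone_cluster", "speech_like")


@dataclass(frozen=True)
class SnoreClipParams:
    """One sleeper's snore signature.

    ``fundamental_hz`` must lie in the 200–1000 Hz snore band.  ``burst_rate``
    is bursts per second at breathing pace (~0.2–0.5 Hz).  ``jitter`` is the
    relative SD of burst spacing; the default 0 keeps the signature
    stereotyped so independently seeded clips from the same parameters match.
    """

    fundamental_hz: float = 220.0
    burst_rate: float = 0.35
    duration: float = 5.0
    harmonics: int = 8
    jitter: float = 0.0
    burst_seconds: float = 1.2
    breath_noise_db: float = -20.0
    seed: int = 0
    sample_rate: int = CANONICAL_RATE

    def __post_init__(self) -> None:
        lo, hi = SNORE_BAND_HZ
        if not (lo <= self.fundamental_hz <= hi):
            raise ValueError(
                f"fundamental {self.fundamental_hz} Hz outside snore band {SNORE_BAND_HZ}")


@dataclass(frozen=True)
class NightParams:
    """Conditions for one synthetic night.

    ``target_ahi`` plants ``round(target_ahi * total_hours)`` respiratory
    events, split evenly between apneas and hypopneas.  ``noise_scale=0``
    gives noiseless traces the scorer must recover exactly; 1 applies the
    documented default noise (flow SD 0.02, SpO2 SD 0.1%, HR SD 2 bpm).
    """

    total_hours: float = 6.0
    target_ahi: float = 20.0
    supine_fraction: float = 0.4
    rem_fraction: float = 0.2
    coupling_probability: float = 0.8
    noise_scale: float = 1.0
    trace_hz: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("supine_fraction", "rem_fraction", "coupling_probability"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.target_ahi < 0 or self.total_hours <= 0:
            raise ValueError("target_ahi must be >= 0 and total_hours > 0")


_PARTIAL_STAGGER_S = 0.06  # onset lag per partial; gives the burst its "flutter"


def gen_snore_clip(params: SnoreClipParams = SnoreClipParams()) -> AudioSignal:
    """Harmonic burst train: partial k at amplitude 1/k under a Hann envelope.

    Each partial's envelope onset lags the previous one by a fixed 60 ms —
    the flutter of soft-tissue vibration — so the landmarks of one burst
    spread over several spectrogram frames.  The stagger is deterministic
    (a property of the signature, not of the seed), which keeps clips from
    the same parameters alignable in the fingerprint domain.
    """
    rng = np.random.default_rng(params.seed)
    sr, dur = params.sample_rate, params.duration
    n = int(round(dur * sr))
    t = np.arange(n) / sr
    x = np.zeros(n)
    spacing = 1.0 / params.burst_rate
    burst_len = int(round(params.burst_seconds * sr))
    # sharp inspiratory attack (40 ms) with exponential decay: the energy
    # maximum of each partial sits in a well-defined spectrogram frame
    t_env = np.arange(burst_len) / sr
    attack = np.minimum(t_env / 0.04, 1.0)
    envelope = attack * np.exp(-np.maximum(t_env - 0.04, 0.0) / 0.35)
    stagger = int(round(_PARTIAL_STAGGER_S * sr))
    start = 0.15  # lead-in before the first inspiration
    while start < dur:
        jittered = start + (rng.normal(0.0, params.jitter * spacing)
                            if params.jitter > 0 else 0.0)
        i_burst = int(round(jittered * sr))
        if i_burst >= n:
            break
        amp = 1.0 + 0.1 * rng.uniform(-1.0, 1.0)  # breath-to-breath loudness
        for k in range(1, params.harmonics + 1):
            i0 = i_burst + (k - 1) * stagger
            if i0 >= n:
                break
            seg = slice(i0, min(i0 + burst_len, n))
            tt = t[seg]
            phase = rng.uniform(0, 2 * np.pi)
            tone = (1.0 / k) * np.sin(2 * np.pi * k * params.fundamental_hz * tt + phase)
            x[seg] += amp * envelope[: seg.stop - seg.start] * tone
        start += spacing
    if params.breath_noise_db is not None:
        sig_power = np.mean(x**2)
        noise_power = sig_power * 10 ** (params.breath_noise_db / 10)
        x += rng.normal(0.0, np.sqrt(noise_power), n)
    return normalize_peak(AudioSignal(samples=x, sample_rate=sr))


def gen_nonsnore_clip(kind: str, duration: float = 5.0, seed: int = 0,
                      sample_rate: int = CANONICAL_RATE) -> AudioSignal:
    """Negative-class distractors: broadband, swept, tonal and speech-like."""
    rng = np.random.default_rng(seed)
    n = int(round(duration * sample_rate))
    t = np.arange(n) / sample_rate
    if kind == "white_noise":
        x = rng.standard_normal(n)
    elif kind == "chirp":
        x = sps.chirp(t, f0=100.0, f1=4000.0, t1=duration, method="linear")
    elif kind == "tone_cluster":
        freqs = (1510.0, 2330.0, 3170.0)  # above the snore band, inharmonic
        x = sum(np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi)) for f in freqs)
    elif kind == "speech_like":
        # glottal-rate pulse train through formant resonators that hop every 80 ms
        pulses = np.zeros(n)
        pulses[:: int(sample_rate / 120)] = 1.0
        x = np.zeros(n)
        seg_len = int(0.08 * sample_rate)
        for s in range(0, n, seg_len):
            segment = pulses[s: s + seg_len]
            y = segment
            for f_center in (rng.uniform(300, 800), rng.uniform(900, 2300)):
                bw = 120.0
                r = np.exp(-np.pi * bw / sample_rate)
                theta = 2 * np.pi * f_center / sample_rate
                b, a = [1.0], [1.0, -2 * r * np.cos(theta), r * r]
                y = sps.lfilter(b, a, y)
            x[s: s + seg_len] = y
    else:
        raise ValueError(f"unknown non-snore kind {kind!r}; "
                         f"choose from {NONSNORE_KINDS}")
    return normalize_peak(AudioSignal(samples=x, sample_rate=sample_rate))


def degrade(signal: AudioSignal, kind: str, level: float | None = None,
            seed: int = 0) -> AudioSignal:
    """Controlled degradations: additive noise at a target SNR (dB),
    amplitude clipping at a ceiling, or a resample round trip."""
    if kind == "additive_noise":
        if level is None:  # infinite SNR
            return signal
        rng = np.random.default_rng(seed)
        sig_power = np.mean(signal.samples**2)
        noise_power = sig_power / 10 ** (level / 10)
        noisy = signal.samples + rng.normal(0.0, np.sqrt(noise_power),
                                            signal.samples.shape)
        return AudioSignal(samples=noisy, sample_rate=signal.sample_rate)
    if kind == "clip":
        if level is None or not (0 < level <= 1):
            raise ValueError("clip level must lie in (0, 1]")
        return AudioSignal(samples=np.clip(signal.samples, -level, level),
                           sample_rate=signal.sample_rate)
    if kind == "resample_roundtrip":
        if level is None or level <= 0:
            raise ValueError("resample_roundtrip level must be a positive rate")
        down = resample(signal, int(level))
        back = resample(down, signal.sample_rate)
        # pad/trim the polyphase edge so length is preserved
        n = len(signal)
        samples = np.zeros(n)
        m = min(n, len(back))
        samples[:m] = back.samples[:m]
        return AudioSignal(samples=samples, sample_rate=signal.sample_rate)
    raise ValueError(f"unknown degradation kind {kind!r}")


@dataclass(frozen=True)
class SnoreEpisode:
    start_s: float
    duration_s: float
    kind: str
    seed: int


@dataclass(frozen=True)
class NightBundle:
    airflow: Trace
    spo2: Trace
    heart_rate: Trace
    position: Trace  # 1 = supine, 0 = lateral
    stage: Trace  # 1 = REM, 0 = NREM
    arousals: list[float]
    planted_events: list[RespiratoryEvent]
    audio_schedule: list[SnoreEpisode]
    params: NightParams = field(repr=False, default=NightParams())

    @property
    def planted_ahi(self) -> float:
        return len(self.planted_events) / self.params.total_hours


# desaturation / heart-rate response shapes (invented for test realism,
# not physiological claims): 4% default dip, -15 bpm during events,
# +20 bpm rebound for 10 s after
_DESAT_MIN, _DESAT_MAX = 3.5, 6.0
_HR_DIP_BPM, _HR_REBOUND_BPM, _HR_REBOUND_S = 15.0, 20.0, 10.0
_EVENT_MIN_S, _EVENT_MAX_S = 12, 24
_EVENT_GAP_S = 60.0
_AROUSAL_ONLY_PROB = 0.3


def gen_night(params: NightParams = NightParams()) -> NightBundle:
    """Build one synthetic night; deterministic per seed.

    Raises ``ValueError`` when ``target_ahi`` cannot fit ``total_hours``
    given the event-duration and spacing constraints.
    """
    rng = np.random.default_rng(params.seed)
    total_s = params.total_hours * 3600.0
    dt = 1.0 / params.trace_hz
    n = int(round(total_s * params.trace_hz))
    times = np.arange(n) * dt

    n_events = int(round(params.target_ahi * params.total_hours))
    slot = total_s / n_events if n_events else total_s
    if n_events and slot < _EVENT_MAX_S + _EVENT_GAP_S:
        raise ValueError(
            f"target_ahi {params.target_ahi} infeasible for "
            f"{params.total_hours} h: events would overlap")

    flow = np.ones(n)
    spo2 = np.full(n, 96.0)
    hr = np.full(n, 60.0)
    position = np.zeros(n)
    stage = np.zeros(n)

    # supine block mid-night, REM block at the end (REM clusters late)
    sup0 = int(0.3 * n)
    position[sup0: sup0 + int(params.supine_fraction * n)] = 1.0
    if params.rem_fraction > 0:
        stage[n - int(params.rem_fraction * n):] = 1.0

    events: list[RespiratoryEvent] = []
    arousals: list[float] = []
    schedule: list[SnoreEpisode] = []
    for k in range(n_events):
        dur = int(rng.integers(_EVENT_MIN_S, _EVENT_MAX_S + 1))
        lead = _EVENT_GAP_S / 2
        start = k * slot + lead + rng.uniform(0, slot - dur - _EVENT_GAP_S)
        start = round(start * params.trace_hz) / params.trace_hz
        i0, i1 = int(round(start * params.trace_hz)), None
        i1 = i0 + int(round(dur * params.trace_hz))
        kind = "apnea" if k % 2 == 0 else "hypopnea"
        if kind == "apnea":
            flow[i0:i1] = 0.0
            desat = True
        else:
            flow[i0:i1] = 0.4  # 60% reduction: between the 10% cut and 50%
            desat = rng.uniform() >= _AROUSAL_ONLY_PROB
            if not desat:
                arousals.append(start + dur / 2.0)
        if desat:
            drop = rng.uniform(_DESAT_MIN, _DESAT_MAX)
            _apply_desat(spo2, times, start, start + dur, drop)
        _apply_hr_response(hr, times, start, start + dur)
        ctx = {"supine": bool(position[i0] == 1.0), "rem": bool(stage[i0] == 1.0)}
        events.append(RespiratoryEvent(kind=kind, start=float(start),
                                       duration=float(dur), context=ctx))
        if rng.uniform() < params.coupling_probability:
            schedule.append(SnoreEpisode(start_s=max(0.0, start - 30.0),
                                         duration_s=20.0, kind="snore",
                                         seed=int(rng.integers(0, 2**31 - 1))))

    if params.noise_scale > 0:
        s = params.noise_scale
        flow += rng.normal(0.0, 0.02 * s, n)
        spo2 = np.clip(spo2 + rng.normal(0.0, 0.1 * s, n), 0.0, 100.0)
        hr += rng.normal(0.0, 2.0 * s, n)

    return NightBundle(
        airflow=Trace(times=times, values=flow),
        spo2=Trace(times=times, values=spo2),
        heart_rate=Trace(times=times, values=hr),
        position=Trace(times=times, values=position),
        stage=Trace(times=times, values=stage),
        arousals=arousals,
        planted_events=events,
        audio_schedule=schedule,
        params=params,
    )


def _apply_desat(spo2: np.ndarray, times: np.ndarray,
                 start: float, end: float, drop: float) -> None:
    """Ramp down over the event, reach the nadir ~5 s after it, recover by +20 s."""
    nadir_t, recover_t = end + 5.0, end + 20.0
    down = (times >= start) & (times < nadir_t)
    spo2[down] -= drop * (times[down] - start) / (nadir_t - start)
    up = (times >= nadir_t) & (times < recover_t)
    spo2[up] -= drop * (recover_t - times[up]) / (recover_t - nadir_t)


def _apply_hr_response(hr: np.ndarray, times: np.ndarray,
                       start: float, end: float) -> None:
    during = (times >= start) & (times < end)
    hr[during] -= _HR_DIP_BPM
    after = (times >= end) & (times < end + _HR_REBOUND_S)
    hr[after] += _HR_REBOUND_BPM
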