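"""Snore/non-snore decisions for clips and for a sliding-window stream.

The decision rule is discriminative: a clip is a snore when its best match
against a snore-labelled template clears the aligned-hit threshold *and*
beats the best match against any other-labelled template.  The default
analysis window is 3.4 s — the end-to-end decision latency of the wearable
pipeline this models — slid in 1 s hops.
"""

from __future__ import annotations

from dataclasses import dataclass

from snorefp.audio_io import AudioSignal
from snorefp.fingerprint import (
    PairingParams,
    SignalTooShortError,
    SpectrogramParams,
    fingerprint_signal,
)
from snorefp.matcher import EmptyDatabaseError, FingerprintDB, match

DEFAULT_THRESHOLD = 5  # aligned hash hits
DEFAULT_WINDOW_SECONDS = 3.4
DEFAULT_HOP_SECONDS = 1.0


@dataclass(frozen=True)
class SnoreDecision:
    is_snore: bool
    score: int
    matched_track: str | None


@dataclass(frozen=True)
class DetectionEvent:
    """One coalesced run of snore-positive analysis windows."""

    onset_time: float
    decision: SnoreDecision
    window: tuple[float, float]


def _fingerprint_kwargs(spec_params, pairing):
    kw = {}
    if spec_params is not None:
        kw["spec_params"] = spec_params
    if pairing is not None:
        kw["pairing"] = pairing
    return kw


def classify_clip(db: FingerprintDB, signal: AudioSignal,
                  threshold: int = DEFAULT_THRESHOLD,
                  spec_params: SpectrogramParams | None = None,
                  pairing: PairingParams | None = None,
                  require_snore_beats_other: bool = True) -> SnoreDecision:
    """Match a clip against the template database and threshold the hits.

    With ``require_snore_beats_other=False`` the rule degrades gracefully to
    a snore-template-only database: any aligned score >= threshold fires.
    """
    if not any(t["label"] == "snore" for t in db.tracks.values()):
        raise EmptyDatabaseError("database holds no snore-labelled track")
    try:
        hashes = fingerprint_signal(signal, **_fingerprint_kwargs(spec_params, pairing))
    except SignalTooShortError:
        hashes = []
    if not hashes:
        return SnoreDecision(is_snore=False, score=0, matched_track=None)
    results = match(db, hashes, top_k=len(db.tracks))
    best_snore = next((r for r in results if r.label == "snore"), None)
    best_other = next((r for r in results if r.label != "snore"), None)
    snore_score = best_snore.score if best_snore else 0
    other_score = best_other.score if best_other else 0
    is_snore = snore_score >= threshold
    if require_snore_beats_other:
        is_snore = is_snore and snore_score >= other_score
    return SnoreDecision(
        is_snore=is_snore,
        score=snore_score,
        matched_track=best_snore.track_id if (best_snore and is_snore) else None,
    )


def detect_stream(db: FingerprintDB, stream: AudioSignal,
                  window_seconds: float = DEFAULT_WINDOW_SECONDS,
                  hop_seconds: float = DEFAULT_HOP_SECONDS,
                  threshold: int = DEFAULT_THRESHOLD,
                  spec_params: SpectrogramParams | None = None,
                  pairing: PairingParams | None = None) -> list[DetectionEvent]:
    """Slide an analysis window over the stream and coalesce positives.

    Consecutive positive windows (gap < one hop) merge into a single event
    whose onset is the start of the first positive window and whose reported
    decision is the highest-scoring window in the run.
    """
    rate = stream.sample_rate
    win = int(round(window_seconds * rate))
    hop = int(round(hop_seconds * rate))
    if len(stream) < win:
        raise SignalTooShortError(
            f"stream of {len(stream)} samples shorter than one "
            f"{window_seconds} s analysis window")
    events: list[DetectionEvent] = []
    run_start: float | None = None
    run_best: SnoreDecision | None = None
    for start in range(0, len(stream) - win + 1, hop):
        t0 = start / rate
        chunk = AudioSignal(samples=stream.samples[start:start + win],
                            sample_rate=rate)
        decision = classify_clip(db, chunk, threshold=threshold,
                                 spec_params=spec_params, pairing=pairing)
        if decision.is_snore:
            if run_start is None:
                run_start, run_best = t0, decision
            elif decision.score > run_best.score:
                run_best = decision
        elif run_start is not None:
            events.append(DetectionEvent(
                onset_time=run_start, decision=run_best,
                window=(run_start, run_start + window_seconds)))
            run_start = run_best = None
    if run_start is not None:
        events.append(DetectionEvent(
            onset_time=run_start, decision=run_best,
            window=(run_start, run_start + window_seconds)))
    return events
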