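"""Fingerprint database and offset-histogram matching.

Tokens index postings of ``(track_id, anchor_time)``.  A query matches a
track when many of its hashes land on the same token at a *consistent* time
offset: the score of a track is the height of the mode of the histogram of
``db_anchor_time - query_anchor_time`` over all token hits, counting each
query hash at most once per offset.  A genuine match produces a sharp mode;
chance collisions scatter across offsets.

The on-disk store is a single JSON file with a versioned header mapping each
token to its packed postings — human-readable, so it doubles as the debug
export.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from snorefp.fingerprint import DEFAULT_TRUNCATION, FingerprintHash

DB_FORMAT_VERSION = 1


class DuplicateTrackError(ValueError):
    pass


class EmptyDatabaseError(ValueError):
    pass


@dataclass
class FingerprintDB:
    """In-memory inverted index: token -> [(track_id, anchor_time), ...]."""

    token_length: int = DEFAULT_TRUNCATION
    index: dict[str, list[tuple[str, int]]] = field(default_factory=dict)
    tracks: dict[str, dict] = field(default_factory=dict)

    def n_postings(self) -> int:
        return sum(len(v) for v in self.index.values())


@dataclass(frozen=True)
class MatchResult:
    track_id: str
    score: int
    best_offset: int
    label: str


def index_track(db: FingerprintDB, track_id: str, label: str,
                hashes: Iterable[FingerprintHash],
                metadata: dict | None = None) -> FingerprintDB:
    """Add a track's hashes to the index; mutates and returns ``db``."""
    if track_id in db.tracks:
        raise DuplicateTrackError(f"track {track_id!r} already indexed")
    hashes = list(hashes)
    for h in hashes:
        if len(h.token) != db.token_length:
            raise ValueError(
                f"token length {len(h.token)} != configured {db.token_length}")
        db.index.setdefault(h.token, []).append((track_id, h.anchor_time))
    db.tracks[track_id] = {"label": label, "n_hashes": len(hashes),
                           **(metadata or {})}
    return db


def match(db: FingerprintDB, query_hashes: list[FingerprintHash],
          top_k: int = 5) -> list[MatchResult]:
    """Score every candidate track by its best-aligned hit count.

    For each track the score is ``max over offsets d`` of the number of
    distinct query hashes h with a posting at ``anchor_time = h.anchor_time
    + d``.  Ties between tracks break lexicographically on track_id; ties
    between offsets within a track take the smallest offset.
    """
    if not db.tracks:
        raise EmptyDatabaseError("cannot match against an empty database")
    # (track, offset) -> set of query-hash positions already credited
    hits: dict[tuple[str, int], set[int]] = {}
    for qi, h in enumerate(query_hashes):
        for track_id, t in db.index.get(h.token, ()):  # token miss: no postings
            hits.setdefault((track_id, t - h.anchor_time), set()).add(qi)
    best: dict[str, tuple[int, int]] = {tid: (0, 0) for tid in db.tracks}
    for (tid, offset), qset in hits.items():
        score = len(qset)
        cur_score, cur_off = best[tid]
        if score > cur_score or (score == cur_score and offset < cur_off):
            best[tid] = (score, offset)
    ranked = sorted(best.items(), key=lambda kv: (-kv[1][0], kv[0]))
    return [MatchResult(track_id=tid, score=score, best_offset=offset,
                        label=db.tracks[tid]["label"])
            for tid, (score, offset) in ranked[:top_k]]


def save_db(db: FingerprintDB, path: str | Path) -> None:
    payload = {
        "format": "snorefp-db",
        "version": DB_FORMAT_VERSION,
        "token_length": db.token_length,
        "tracks": db.tracks,
        "index": {tok: [[tid, int(t)] for tid, t in postings]
                  for tok, postings in db.index.items()},
    }
    Path(path).write_text(json.dumps(payload))


def load_db(path: str | Path) -> FingerprintDB:
    payload = json.loads(Path(path).read_text())
    if payload.get("format") != "snorefp-db":
        raise ValueError(f"{path}: not a snorefp database")
    if payload.get("version") != DB_FORMAT_VERSION:
        raise ValueError(f"{path}: unsupported db version {payload.get('version')}")
    db = FingerprintDB(token_length=int(payload["token_length"]))
    db.tracks = dict(payload["tracks"])
    db.index = {tok: [(tid, int(t)) for tid, t in postings]
                for tok, postings in payload["index"].items()}
    return db


def export_json(db: FingerprintDB, path: str | Path) -> None:
    """Debug export; identical schema to the store, pretty-printed."""
    save_db(db, path)
    Path(path).write_text(json.dumps(json.loads(Path(path).read_text()), indent=2))
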