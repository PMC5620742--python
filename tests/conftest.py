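"""Shared fixtures and independent oracles used across the suite."""

from __future__ import annotations

import numpy as np
import pytest

from snorefp.fingerprint import ConstellationMap, Peak, Spectrogram
from snorefp.matcher import FingerprintDB


# ---------------------------------------------------------------- oracles


def naive_dft_magnitudes(frame: np.ndarray) -> np.ndarray:
    """Direct O(N^2) DFT magnitude of one windowed frame (rfft bins)."""
    n = len(frame)
    k = np.arange(n // 2 + 1)
    basis = np.exp(-2j * np.pi * np.outer(k, np.arange(n)) / n)
    return np.abs(basis @ frame)


def brute_force_peaks(magnitudes: np.ndarray, dt: int, df: int,
                      floor) -> set[tuple[int, int]]:
    """Exhaustive strict-local-maximum scan via padded sliding windows."""
    m = np.asarray(magnitudes, dtype=float)
    floor_arr = np.broadcast_to(np.asarray(floor, dtype=float).reshape(-1, 1)
                                if np.ndim(floor) == 1 else floor, m.shape)
    padded = np.pad(m, ((dt, dt), (df, df)), constant_values=-np.inf)
    windows = np.lib.stride_tricks.sliding_window_view(
        padded, (2 * dt + 1, 2 * df + 1)).copy()
    windows[:, :, dt, df] = -np.inf  # exclude the cell itself
    neighbor_max = windows.max(axis=(2, 3))
    hits = np.argwhere((m > neighbor_max) & (m >= floor_arr))
    return {(int(t), int(f)) for t, f in hits}


def brute_force_pairs(peaks, min_dt, max_dt, max_df):
    """All-pairs target-zone filter (no fan-out limit)."""
    out = []
    for a in peaks:
        for b in peaks:
            dt = b.frame_index - a.frame_index
            if min_dt <= dt <= max_dt and abs(b.bin_index - a.bin_index) <= max_df:
                out.append((a, b))
    return out


def brute_force_match_score(db: FingerprintDB, track_id: str,
                            query_hashes) -> tuple[int, int]:
    """O(|Q| * postings) rescan of one track without using the inverted index.

    Returns (score, best_offset); (0, 0) when nothing matches.
    """
    postings = [(tok, t) for tok, plist in db.index.items()
                for tid, t in plist if tid == track_id]
    per_offset: dict[int, set[int]] = {}
    for qi, h in enumerate(query_hashes):
        for tok, t in postings:
            if tok == h.token:
                per_offset.setdefault(t - h.anchor_time, set()).add(qi)
    if not per_offset:
        return 0, 0
    best = max(per_offset.items(), key=lambda kv: (len(kv[1]), -kv[0]))
    score = len(best[1])
    offset = min(off for off, s in per_offset.items() if len(s) == score)
    return score, offset


def make_spectrogram(magnitudes: np.ndarray) -> Spectrogram:
    nf, nb = magnitudes.shape
    return Spectrogram(magnitudes=np.asarray(magnitudes, dtype=float),
                       frame_times=np.arange(nf, dtype=float),
                       bin_freqs=np.arange(nb, dtype=float))


def make_cmap(coords) -> ConstellationMap:
    peaks = tuple(sorted(Peak(int(t), int(f), 1.0) for t, f in coords))
    return ConstellationMap(peaks=peaks)


# ---------------------------------------------------------------- fixtures


@pytest.fixture(scope="session")
def snore_template_db() -> FingerprintDB:
    """Twenty default-signature snore templates (seeds 100-119) plus
    non-snore distractors, shared across detector tests."""
    from snorefp.fingerprint import fingerprint_signal
    from snorefp.matcher import index_track
    from snorefp.synthetic_data import (
        NONSNORE_KINDS,
        SnoreClipParams,
        gen_nonsnore_clip,
        gen_snore_clip,
    )

    db = FingerprintDB()
    for i in range(20):
        clip = gen_snore_clip(SnoreClipParams(seed=100 + i))
        index_track(db, f"snore_{i:02d}", "snore", fingerprint_signal(clip))
    for j, kind in enumerate(NONSNORE_KINDS):
        clip = gen_nonsnore_clip(kind, duration=5.0, seed=900 + j)
        index_track(db, f"other_{j:02d}", "other", fingerprint_signal(clip))
    return db
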