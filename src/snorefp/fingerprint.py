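"""Spectrogram-landmark audio fingerprinting.

The pipeline follows the classic constellation-map recipe: short-time Fourier
magnitudes -> strict local-maximum peaks ("stars") -> anchor/target peak pairs
inside a bounded time-frequency zone -> truncated SHA-1 tokens over
``(anchor_bin, target_bin, dt_frames)``.  Because a token encodes only bin
numbers and a frame *difference*, the fingerprint of a clip is invariant under
time shifts except for the anchor timestamps carried alongside — which is what
lets the matcher align query and database tracks by a common offset.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import maximum_filter

from snorefp.audio_io import CANONICAL_RATE, AudioSignal, resample, to_mono

DEFAULT_TRUNCATION = 20  # hex chars = 80 bits; collisions negligible at desk scale


class SignalTooShortError(ValueError):
    """Signal shorter than one analysis window."""


@dataclass(frozen=True)
class SpectrogramParams:
    """STFT analysis parameters.

    Defaults: 4096-sample window (~93 ms at 44.1 kHz), 50% overlap, Hann
    taper, log magnitude.  ~93 ms resolves the 200–1000 Hz snore band with
    ~10.8 Hz bins while keeping frames short against burst timing.
    """

    window_length: int = 4096
    hop_length: int = 2048
    window_function: str = "hann"
    magnitude_scale: str = "log"

    def __post_init__(self) -> None:
        if not (0 < self.hop_length <= self.window_length):
            raise ValueError("require 0 < hop_length <= window_length")
        if self.magnitude_scale not in ("linear", "log"):
            raise ValueError(f"unknown magnitude_scale {self.magnitude_scale!r}")


@dataclass(frozen=True)
class Spectrogram:
    """Time-frequency magnitude matrix: rows are frames, columns frequency bins."""

    magnitudes: np.ndarray  # [frame, bin], non-negative
    frame_times: np.ndarray  # seconds, left edge of each window
    bin_freqs: np.ndarray  # Hz, ascending, <= Nyquist

    @property
    def n_frames(self) -> int:
        return self.magnitudes.shape[0]

    @property
    def n_bins(self) -> int:
        return self.magnitudes.shape[1]


@dataclass(frozen=True, order=True)
class Peak:
    frame_index: int
    bin_index: int
    magnitude: float = field(compare=False)


@dataclass(frozen=True)
class ConstellationMap:
    """Sparse set of spectrogram peaks, sorted by (frame, bin), no duplicates."""

    peaks: tuple[Peak, ...]

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)


@dataclass(frozen=True)
class PairingParams:
    """Anchor-target pairing zone.

    Each peak anchors up to ``fan_out`` later peaks whose frame lag lies in
    ``[min_dt_frames, max_dt_frames]`` and whose bin offset is within
    ``max_df_bins`` (symmetric by default; ``targets_above_only`` restricts
    to targets at or above the anchor frequency).
    """

    fan_out: int = 5
    min_dt_frames: int = 1
    max_dt_frames: int = 60
    max_df_bins: int = 120
    targets_above_only: bool = False

    def __post_init__(self) -> None:
        if self.fan_out < 1:
            raise ValueError("fan_out must be >= 1")
        if not (0 < self.min_dt_frames <= self.max_dt_frames):
            raise ValueError("require 0 < min_dt_frames <= max_dt_frames")


@dataclass(frozen=True)
class FingerprintHash:
    """Truncated SHA-1 token over (anchor_bin, target_bin, dt_frames) + anchor frame."""

    token: str
    anchor_time: int


def _window(params: SpectrogramParams) -> np.ndarray:
    from scipy.signal import get_window

    return get_window(params.window_function, params.window_length, fftbins=True)


def compute_spectrogram(signal: AudioSignal,
                        params: SpectrogramParams = SpectrogramParams()) -> Spectrogram:
    """Magnitude STFT with frame k covering samples [k*hop, k*hop + window).

    Log scale stores ``log1p(|X|)``, which keeps magnitudes non-negative and
    compresses dynamic range so the peak floor percentile behaves across
    loud and quiet clips alike.
    """
    x = signal.samples
    if x.ndim != 1:
        x = to_mono(signal).samples
    n, w, h = len(x), params.window_length, params.hop_length
    if n < w:
        raise SignalTooShortError(
            f"signal has {n} samples but one window needs {w}")
    n_frames = (n - w) // h + 1
    idx = np.arange(w)[None, :] + h * np.arange(n_frames)[:, None]
    frames = x[idx] * _window(params)[None, :]
    mags = np.abs(np.fft.rfft(frames, axis=1))
    if params.magnitude_scale == "log":
        mags = np.log1p(mags)
    frame_times = (h * np.arange(n_frames)) / signal.sample_rate
    bin_freqs = np.fft.rfftfreq(w, d=1.0 / signal.sample_rate)
    return Spectrogram(magnitudes=mags, frame_times=frame_times, bin_freqs=bin_freqs)


def find_peaks(spec: Spectrogram,
               neighborhood: tuple[int, int] = (15, 15),
               floor: float | np.ndarray = 0.0) -> ConstellationMap:
    """Strict local maxima of the magnitude matrix.

    A cell is a peak iff it is strictly greater than every other cell within
    ``(+-dt_frames, +-df_bins)`` and at least ``floor`` (scalar, or one value
    per frame).  Strictness means plateaus/ties yield no peak, which makes
    the constellation deterministic.
    """
    dt, df = neighborhood
    if dt < 1 or df < 1:
        raise ValueError("neighborhood radii must be >= 1")
    m = spec.magnitudes
    if m.size == 0:
        return ConstellationMap(peaks=())
    # max over the full rectangle is separable and fast; strictness is then
    # verified per candidate against the neighborhood excluding the cell itself
    full_max = maximum_filter(m, size=(2 * dt + 1, 2 * df + 1),
                              mode="constant", cval=-np.inf)
    floor_arr = np.asarray(floor, dtype=float)
    if floor_arr.ndim == 1:
        floor_arr = floor_arr[:, None]
    candidates = np.argwhere((m >= floor_arr) & (m == full_max) & (m > 0))
    peaks = []
    nf, nb = m.shape
    for t, f in candidates:
        t0, t1 = max(0, t - dt), min(nf, t + dt + 1)
        f0, f1 = max(0, f - df), min(nb, f + df + 1)
        block = m[t0:t1, f0:f1]
        # strict: the candidate must be the unique attainer of the block max
        if np.count_nonzero(block == m[t, f]) == 1:
            peaks.append(Peak(int(t), int(f), float(m[t, f])))
    peaks.sort()
    return ConstellationMap(peaks=tuple(peaks))


def frame_percentile_floor(spec: Spectrogram, percentile: float = 60.0) -> np.ndarray:
    """Per-frame magnitude floor at the given percentile (default 60th)."""
    return np.percentile(spec.magnitudes, percentile, axis=1)


def pair_peaks(cmap: ConstellationMap,
               params: PairingParams = PairingParams()) -> list[tuple[Peak, Peak]]:
    """Pair every peak (anchor) with up to ``fan_out`` peaks in its target zone.

    Targets are taken in (frame, bin) order, which the sorted constellation
    provides for free.
    """
    peaks = cmap.peaks
    pairs: list[tuple[Peak, Peak]] = []
    for i, anchor in enumerate(peaks):
        taken = 0
        for target in peaks[i + 1:]:
            dt = target.frame_index - anchor.frame_index
            if dt > params.max_dt_frames:
                break  # sorted by frame: no later peak can qualify
            if dt < params.min_dt_frames:
                continue
            dfb = target.bin_index - anchor.bin_index
            if abs(dfb) > params.max_df_bins:
                continue
            if params.targets_above_only and dfb < 0:
                continue
            pairs.append((anchor, target))
            taken += 1
            if taken >= params.fan_out:
                break
    return pairs


def hash_pair(anchor: Peak, target: Peak,
              truncation: int = DEFAULT_TRUNCATION) -> FingerprintHash:
    """SHA-1 over the canonical string ``"f_anchor|f_target|dt"``, truncated."""
    dt = target.frame_index - anchor.frame_index
    payload = f"{anchor.bin_index}|{target.bin_index}|{dt}".encode()
    token = hashlib.sha1(payload).hexdigest()[:truncation]
    return FingerprintHash(token=token, anchor_time=anchor.frame_index)


def fingerprint_signal(signal: AudioSignal,
                       spec_params: SpectrogramParams = SpectrogramParams(),
                       neighborhood: tuple[int, int] = (15, 15),
                       floor_percentile: float = 60.0,
                       pairing: PairingParams = PairingParams(),
                       truncation: int = DEFAULT_TRUNCATION,
                       target_rate: int = CANONICAL_RATE) -> list[FingerprintHash]:
    """Full pipeline: canonicalise -> spectrogram -> peaks -> pairs -> hashes.

    Deterministic for a fixed input and parameter set.  Silence produces an
    empty list (no cell exceeds zero, so there are no peaks to pair).
    """
    sig = to_mono(signal)
    sig = resample(sig, target_rate)
    spec = compute_spectrogram(sig, spec_params)
    floor = frame_percentile_floor(spec, floor_percentile)
    cmap = find_peaks(spec, neighborhood, floor)
    pairs = pair_peaks(cmap, pairing)
    return [hash_pair(a, t, truncation) for a, t in pairs]
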