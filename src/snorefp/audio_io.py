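"""WAV reading/writing and canonicalisation of audio to mono float at 44.1 kHz.

Internally audio is float64 in [-1, 1]; files are 16-bit PCM RIFF WAV.  The
canonical sample rate is 44,100 Hz — the standard full-audio-band rate, since
human hearing tops out near 22,050 Hz and Nyquist demands twice that.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.io import wavfile
from scipy.signal import resample_poly

CANONICAL_RATE = 44_100

_PCM_SCALE = {
    np.dtype(np.int16): 32768.0,
    np.dtype(np.int32): 2147483648.0,
    np.dtype(np.uint8): 128.0,  # offset binary
}


class AudioFormatError(ValueError):
    """Raised for files that are not PCM WAV or use an unsupported encoding."""


@dataclass(frozen=True)
class AudioSignal:
    """Sampled audio: float amplitudes (nominal range [-1, 1]) at a fixed rate.

    ``samples`` is shape (n,) for mono or (n, channels) for multichannel.
    """

    samples: np.ndarray
    sample_rate: int
    channel_count: int = field(default=1)

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        if self.sample_rate <= 0:
            raise ValueError(f"sample_rate must be positive, got {self.sample_rate}")
        if not np.all(np.isfinite(samples)):
            raise ValueError("samples contain non-finite values")
        if samples.ndim == 1:
            channels = 1
        elif samples.ndim == 2:
            channels = samples.shape[1]
        else:
            raise ValueError("samples must be 1-D (mono) or 2-D (frames x channels)")
        object.__setattr__(self, "samples", samples)
        object.__setattr__(self, "channel_count", channels)

    def __len__(self) -> int:
        return self.samples.shape[0]

    @property
    def duration_seconds(self) -> float:
        return self.samples.shape[0] / self.sample_rate


def read_wav(path: str | Path) -> AudioSignal:
    """Read a PCM WAV file, scaling integer samples to [-1, 1].

    Raises
    ------
    FileNotFoundError
        If the file does not exist.
    AudioFormatError
        For non-WAV files or non-PCM encodings.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    try:
        rate, data = wavfile.read(str(path))
    except ValueError as exc:  # scipy names the offending chunk/format code
        raise AudioFormatError(f"{path}: not a supported PCM WAV ({exc})") from exc
    if data.dtype in _PCM_SCALE:
        scale = _PCM_SCALE[data.dtype]
        if data.dtype == np.uint8:
            samples = (data.astype(np.float64) - 128.0) / scale
        else:
            samples = data.astype(np.float64) / scale
    elif np.issubdtype(data.dtype, np.floating):
        samples = data.astype(np.float64)
    else:
        raise AudioFormatError(f"{path}: unsupported sample format {data.dtype}")
    return AudioSignal(samples=samples, sample_rate=int(rate))


def write_wav(path: str | Path, signal: AudioSignal) -> None:
    """Write a signal as 16-bit PCM, clipping amplitudes to [-1, 1]."""
    scaled = np.round(np.clip(signal.samples, -1.0, 1.0) * 32768.0)
    pcm = np.clip(scaled, -32768, 32767).astype(np.int16)
    wavfile.write(str(Path(path)), signal.sample_rate, pcm)


def to_mono(signal: AudioSignal, mode: str = "mean") -> AudioSignal:
    """Downmix to a single channel.

    ``mode='mean'`` (default) averages channels, preserving energy balance;
    ``mode='first'`` drops all but channel 0.
    """
    if signal.channel_count == 1:
        return signal
    if mode == "mean":
        mono = signal.samples.mean(axis=1)
    elif mode == "first":
        mono = signal.samples[:, 0].copy()
    else:
        raise ValueError(f"unknown downmix mode {mode!r}")
    return AudioSignal(samples=mono, sample_rate=signal.sample_rate)


def resample(signal: AudioSignal, target_rate: int = CANONICAL_RATE) -> AudioSignal:
    """Band-limited polyphase resampling to ``target_rate``.

    Output length is ``round(n * target_rate / sample_rate)`` (exact for
    rational rate ratios, which integer rates always are).
    """
    if target_rate <= 0:
        raise ValueError(f"target_rate must be positive, got {target_rate}")
    if target_rate == signal.sample_rate:
        return signal
    g = math.gcd(int(target_rate), int(signal.sample_rate))
    up, down = target_rate // g, signal.sample_rate // g
    out = resample_poly(signal.samples, up, down, axis=0)
    return AudioSignal(samples=out, sample_rate=int(target_rate))


def normalize_peak(signal: AudioSignal, peak: float = 0.9) -> AudioSignal:
    """Scale so the largest absolute amplitude equals ``peak``; silence passes through."""
    top = np.max(np.abs(signal.samples)) if len(signal) else 0.0
    if top == 0.0:
        return signal
    return AudioSignal(samples=signal.samples * (peak / top),
                       sample_rate=signal.sample_rate)
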