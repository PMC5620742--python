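"""Hierarchical run configuration: dataclass defaults + YAML file + overrides.

Every tunable named in the module docstrings lives here under one of the
sections ``audio``, ``fingerprint``, ``matcher``, ``detector``, ``stimulus``,
``heart_rate``, ``psg``.  Unknown keys in a config file are rejected so typos
fail loudly instead of silently falling back to defaults.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from snorefp.alert_controller import HeartRateConfig, StimulusConfig
from snorefp.audio_io import CANONICAL_RATE
from snorefp.fingerprint import PairingParams, SpectrogramParams


@dataclass(frozen=True)
class AudioConfig:
    target_rate: int = CANONICAL_RATE
    downmix: str = "mean"  # or "first"


@dataclass(frozen=True)
class PeakConfig:
    dt_frames: int = 15
    df_bins: int = 15
    floor_percentile: float = 60.0


@dataclass(frozen=True)
class DetectorConfig:
    window_seconds: float = 3.4
    hop_seconds: float = 1.0
    threshold: int = 5
    require_snore_beats_other: bool = True


@dataclass(frozen=True)
class PsgConfig:
    baseline_window: float = 120.0
    apnea_cut_fraction: float = 0.10
    hypopnea_reduction_fraction: float = 0.50
    min_event_seconds: float = 10.0
    min_spo2_drop: float = 3.0
    spo2_baseline_seconds: float = 30.0
    spo2_lag_seconds: float = 30.0


@dataclass(frozen=True)
class RunConfig:
    audio: AudioConfig = field(default_factory=AudioConfig)
    spectrogram: SpectrogramParams = field(default_factory=SpectrogramParams)
    peaks: PeakConfig = field(default_factory=PeakConfig)
    pairing: PairingParams = field(default_factory=PairingParams)
    detector: DetectorConfig = field(default_factory=DetectorConfig)
    stimulus: StimulusConfig = field(default_factory=StimulusConfig)
    heart_rate: HeartRateConfig = field(default_factory=HeartRateConfig)
    psg: PsgConfig = field(default_factory=PsgConfig)


class UnknownConfigKeyError(ValueError):
    pass


def _build(cls, data: dict, path: str):
    names = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(names)
    if unknown:
        raise UnknownConfigKeyError(
            f"unknown key(s) {sorted(unknown)} under {path or 'top level'}; "
            f"valid keys: {sorted(names)}")
    kwargs = {}
    for key, value in data.items():
        ftype = names[key].type
        if isinstance(value, dict):
            sub_cls = _section_class(cls, key)
            kwargs[key] = _build(sub_cls, value, f"{path}.{key}".lstrip("."))
        else:
            kwargs[key] = value
    return cls(**kwargs)


def _section_class(cls, key: str):
    for f in dataclasses.fields(cls):
        if f.name == key:
            default = f.default_factory() if f.default_factory is not dataclasses.MISSING else f.default
            return type(default)
    raise KeyError(key)


def load_config(path: str | Path | None = None,
                overrides: dict | None = None) -> RunConfig:
    """Load a YAML config; missing file/None means pure defaults."""
    data: dict = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text())
        if loaded is not None:
            if not isinstance(loaded, dict):
                raise ValueError(f"{path}: config must be a mapping")
            data = loaded
    for dotted, value in (overrides or {}).items():
        node = data
        *parents, leaf = dotted.split(".")
        for p in parents:
            node = node.setdefault(p, {})
        node[leaf] = value
    return _build(RunConfig, data, "")


def config_to_dict(cfg: RunConfig) -> dict:
    return dataclasses.asdict(cfg)
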