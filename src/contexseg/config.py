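"""YAML-backed configuration for the end-to-end pipeline.

Plain nested dataclasses with strict validation: unknown keys are
rejected with their key path, defaults are filled in, and
``load_config(dump_config(cfg)) == cfg`` round-trips.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .model import ModelConfig, TrainConfig
from .modifications import ModificationSetting


@dataclass(frozen=True)
class DataConfig:
    """Synthetic cohort parameters (the study conditions)."""

    n_subjects: int = 25
    size: tuple[int, int] = (48, 48)
    noise_sigma: float = 0.03
    variability: float = 0.5
    tr_range: tuple[float, float, float] = (300.0, 800.0, 100.0)
    te_range: tuple[float, float, float] = (10.0, 40.0, 5.0)
    n_protocols: int = 6
    ratio: tuple[int, int, int] = (16, 4, 5)

    def __post_init__(self) -> None:
        if self.n_subjects < sum(self.ratio):
            raise ValueError("n_subjects must cover the split ratio")
        if self.noise_sigma < 0 or self.variability < 0:
            raise ValueError("noise_sigma and variability must be >= 0")
        if self.n_protocols < 1:
            raise ValueError("n_protocols must be >= 1")


@dataclass(frozen=True)
class GridSpec:
    """Modification-grid axes: kind plus shared strength samples."""

    kind: str = "contrast"
    strengths: tuple[int, ...] = (-21, -11, -4, 4, 11, 21)
    n_runs: int = 3

    def __post_init__(self) -> None:
        if self.kind not in ("contrast", "texture"):
            raise ValueError("grid kind must be 'contrast' or 'texture'")
        for s in self.strengths:
            ModificationSetting(self.kind, s)  # validates range
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")


@dataclass(frozen=True)
class SaliencyConfig:
    n_steps: int = 16
    representative_tr_ms: float = 500.0
    representative_te_ms: float = 25.0

    def __post_init__(self) -> None:
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")


@dataclass(frozen=True)
class PipelineConfig:
    seed: int = 0
    data: DataConfig = field(default_factory=DataConfig)
    grid: GridSpec = field(default_factory=GridSpec)
    model: ModelConfig = field(default_factory=lambda: ModelConfig(
        input_size=(48, 48), depth=2, base_channels=8, dropout_rate=0.1))
    train: TrainConfig = field(default_factory=lambda: TrainConfig(
        epochs=60, batch_size=8, learning_rate=5e-3))
    saliency: SaliencyConfig = field(default_factory=SaliencyConfig)

    def __post_init__(self) -> None:
        if tuple(self.model.input_size) != tuple(self.data.size):
            raise ValueError("model.input_size must equal data.size")


_TUPLE_FIELDS = {
    "size", "tr_range", "te_range", "ratio", "strengths", "input_size",
}

_NESTED = {
    "data": DataConfig,
    "grid": GridSpec,
    "saliency": SaliencyConfig,
    "model": ModelConfig,
    "train": TrainConfig,
}


def _build(cls, payload, path: str):
    if not isinstance(payload, dict):
        raise ValueError(f"{path or 'config'}: expected a mapping")
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(payload) - names
    if unknown:
        where = f"{path}." if path else ""
        raise ValueError(
            "unknown config key(s): "
            + ", ".join(sorted(f"{where}{k}" for k in unknown))
        )
    kwargs = {}
    for key, value in payload.items():
        sub = f"{path}.{key}" if path else key
        if cls is PipelineConfig and key in _NESTED:
            kwargs[key] = _build(_NESTED[key], value, sub)
        elif key in _TUPLE_FIELDS:
            kwargs[key] = tuple(value)
        else:
            kwargs[key] = value
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{path or 'config'}: {exc}") from exc


def config_from_dict(payload: dict) -> PipelineConfig:
    """Validate a plain dict (e.g. parsed YAML) into a PipelineConfig."""
    return _build(PipelineConfig, payload or {}, "")


def config_to_dict(cfg: PipelineConfig) -> dict:
    def _plain(obj):
        if dataclasses.is_dataclass(obj):
            return {f.name: _plain(getattr(obj, f.name))
                    for f in dataclasses.fields(obj)}
        if isinstance(obj, tuple):
            return [_plain(v) for v in obj]
        return obj

    return _plain(cfg)


def load_config(path: str | Path) -> PipelineConfig:
    """Load and validate a YAML pipeline configuration file."""
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    return config_from_dict(payload)


def dump_config(cfg: PipelineConfig, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(cfg), fh, sort_keys=False)
    return path
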