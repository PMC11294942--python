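"""Run configuration: a validated YAML schema for end-to-end runs.

A config selects exactly one segmenter (``em`` or ``network``), an input
source (image/mask paths, or a synthetic phantom spec), the preprocessing
stage list, and evaluation options.  Unknown keys are rejected with an error
listing every offender, and omitted fields receive the package defaults
(EM tolerance 1e-3, Adam learning rate 0.001, 70/15/15 split).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig", "ConfigError", "load_config", "save_config"]


class ConfigError(ValueError):
    """Schema violation(s); the message lists every offending key."""


@dataclass
class SyntheticInput:
    n: int = 10
    size: tuple[int, int] = (64, 64)
    n_nodules: tuple[int, int] = (1, 3)
    nodule_radius: tuple[float, float] = (3.0, 8.0)
    noise_sd: float = 2.0


@dataclass
class PreprocessConfig:
    stages: tuple[str, ...] = ()
    window: dict = field(default_factory=lambda: {"center": -600.0, "width": 1500.0})
    clahe: dict = field(default_factory=lambda: {"tile_grid": (8, 8),
                                                 "clip_limit": 0.01, "n_bins": 256})
    wiener: dict = field(default_factory=lambda: {"window": 3, "noise_variance": "auto"})
    resize_to: tuple[int, int] = (128, 128)


@dataclass
class EMSegmenter:
    K: int | None = None  # None: estimate from the intensity histogram
    tol: float = 1e-3
    max_iter: int = 200
    init: str = "quantile"
    shape: float = 4.0


@dataclass
class NetworkSegmenter:
    depth: int = 3
    base_filters: int = 8
    input_size: tuple[int, int] = (64, 64)
    dropout_rate: float = 0.5
    l2_lambda: float = 0.001
    skip_mode: str = "plain"
    epochs: int = 100
    learning_rate: float = 0.001
    batch_size: int = 32
    split_fractions: tuple[float, float, float] = (0.70, 0.15, 0.15)
    threshold: float = 0.5
    checkpoint: str | None = None


@dataclass
class EvaluationConfig:
    metrics: tuple[str, ...] = ("dice", "iou", "pri", "voi", "gce",
                                "accuracy", "sensitivity", "specificity",
                                "precision", "f1")
    roi: str | None = None  # optional path to an ROI mask


@dataclass
class RunConfig:
    seed: int = 0
    output_dir: str = "runs/out"
    log_level: str = "INFO"
    images: tuple[str, ...] = ()
    masks: tuple[str, ...] = ()
    synthetic: SyntheticInput | None = None
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    em: EMSegmenter | None = None
    network: NetworkSegmenter | None = None
    evaluation: EvaluationConfig = field(default_factory=EvaluationConfig)

    def __post_init__(self) -> None:
        if (self.em is None) == (self.network is None):
            raise ConfigError("exactly one segmenter ('em' or 'network') must be configured")
        if not self.images and self.synthetic is None:
            raise ConfigError("an input is required: 'images' paths or a 'synthetic' block")
        if self.masks and len(self.masks) != len(self.images):
            raise ConfigError("'masks' must match 'images' in length")

    @property
    def segmenter_name(self) -> str:
        return "em" if self.em is not None else "network"

    def to_dict(self) -> dict:
        def conv(v):
            if isinstance(v, tuple):
                return [conv(x) for x in v]
            if isinstance(v, dict):
                return {k: conv(x) for k, x in v.items()}
            return v

        d = conv(asdict(self))
        return {k: v for k, v in d.items() if v not in (None, [], {})}


_SECTION_TYPES = {
    "synthetic": SyntheticInput,
    "preprocess": PreprocessConfig,
    "em": EMSegmenter,
    "network": NetworkSegmenter,
    "evaluation": EvaluationConfig,
}

_TUPLE_FIELDS = {"size", "n_nodules", "nodule_radius", "stages", "resize_to",
                 "split_fractions", "input_size", "metrics", "images", "masks",
                 "tile_grid"}


def _deep_tuple(v):
    if isinstance(v, list):
        return tuple(_deep_tuple(x) for x in v)
    if isinstance(v, dict):
        return {k: _deep_tuple(x) for k, x in v.items()}
    return v


def _build_section(cls, data: dict, prefix: str, errors: list[str]):
    valid = {f for f in cls.__dataclass_fields__}
    kwargs = {}
    for k, v in data.items():
        if k not in valid:
            errors.append(f"{prefix}{k}")
            continue
        kwargs[k] = _deep_tuple(v)
    return cls(**kwargs) if not errors else None


def load_config(path_or_dict) -> RunConfig:
    """Parse and validate a YAML run configuration."""
    if isinstance(path_or_dict, (str, Path)):
        with open(path_or_dict) as fh:
            raw = yaml.safe_load(fh) or {}
    else:
        raw = dict(path_or_dict)
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")

    top_valid = set(RunConfig.__dataclass_fields__)
    errors: list[str] = []
    kwargs: dict = {}
    for k, v in raw.items():
        if k not in top_valid:
            errors.append(k)
            continue
        if k in _SECTION_TYPES:
            if not isinstance(v, dict):
                errors.append(f"{k} (expected a mapping)")
                continue
            section = _build_section(_SECTION_TYPES[k], v, f"{k}.", errors)
            if section is not None:
                kwargs[k] = section
        elif k in _TUPLE_FIELDS and isinstance(v, list):
            kwargs[k] = _deep_tuple(v)
        else:
            kwargs[k] = v
    if errors:
        raise ConfigError("unknown or invalid config keys: " + ", ".join(sorted(errors)))
    return RunConfig(**kwargs)


def save_config(cfg: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)
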