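"""Model configuration: one serializable bundle for all layers.

The defaults are the reference four-scale model: 12 orientations, simple
sizes (40, 60, 88, 120) with aspect ratios (0.7, 1.4, 2.15, 3) and width
ratio 2.5; endstopped gains (1.5, 1.25, 1, 3) with centre gain 1; logistic
saturation alpha 0.01, beta divisor 8.5; 10 px radial and pi/45 angular
shape bins.  An alternate parameter set used for illustrating curvature
discrimination (sizes 40/80/100/120, AR 1.15/2/3/4, gains 0.7/0.8/1/2) is
available as ``fig_curvature_config()``.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field, fields, replace

import yaml

from .curvature import CurvatureConfig
from .endstopped import EndstoppedConfig
from .frontend import FilterBankConfig
from .shape import PolarBinGrid

__all__ = ["ModelConfig", "load_config", "save_config", "fig_curvature_config"]


@dataclass(frozen=True)
class ModelConfig:
    bank: FilterBankConfig = field(default_factory=FilterBankConfig)
    endstopped: EndstoppedConfig = field(default_factory=EndstoppedConfig)
    curvature: CurvatureConfig = field(default_factory=CurvatureConfig)
    grid: PolarBinGrid = field(default_factory=PolarBinGrid)
    position_sigma: tuple[float, float] = (1.0, 1.0)
    curvature_sigma: float = 1.0
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "position_sigma", tuple(self.position_sigma))
        if len(self.endstopped.flank_gains) < self.bank.n_scales:
            raise ValueError("endstopped flank_gains must cover every scale")
        if len(self.endstopped.sign_displacement_fractions) < self.bank.n_scales:
            raise ValueError(
                "endstopped sign_displacement_fractions must cover every scale"
            )


_SECTIONS = {
    "bank": FilterBankConfig,
    "endstopped": EndstoppedConfig,
    "curvature": CurvatureConfig,
    "grid": PolarBinGrid,
}


def _build_section(cls, data: dict, where: str):
    allowed = {f.name for f in fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ValueError(f"unknown keys in {where}: {sorted(unknown)}")
    return cls(**data)


def load_config(path) -> ModelConfig:
    """Load a YAML/JSON model configuration; absent fields take defaults.

    Unknown keys raise with the offending names so typos do not silently
    fall back to defaults.
    """
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        return ModelConfig()
    if not isinstance(data, dict):
        raise ValueError("config file must contain a mapping")
    top_allowed = {f.name for f in fields(ModelConfig)}
    unknown = set(data) - top_allowed
    if unknown:
        raise ValueError(f"unknown top-level config keys: {sorted(unknown)}")
    kwargs = {}
    for name, cls in _SECTIONS.items():
        if name in data:
            kwargs[name] = _build_section(cls, dict(data[name]), name)
    for name in ("position_sigma", "curvature_sigma", "seed"):
        if name in data:
            kwargs[name] = data[name]
    return ModelConfig(**kwargs)


def _plain(obj):
    """Recursively convert tuples to lists for YAML serialization."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    return obj


def save_config(config: ModelConfig, path) -> None:
    data = _plain(
        {
            "bank": asdict(config.bank),
            "endstopped": asdict(config.endstopped),
            "curvature": asdict(config.curvature),
            "grid": asdict(config.grid),
            "position_sigma": list(config.position_sigma),
            "curvature_sigma": config.curvature_sigma,
            "seed": config.seed,
        }
    )
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def fig_curvature_config() -> ModelConfig:
    """Alternate parameter set of the curvature-discrimination illustration."""
    return ModelConfig(
        bank=FilterBankConfig(
            sizes=(40, 80, 100, 120), aspect_ratios=(1.15, 2.0, 3.0, 4.0)
        ),
        endstopped=EndstoppedConfig(flank_gains=(0.7, 0.8, 1.0, 2.0)),
    )
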