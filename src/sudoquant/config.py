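"""Run configuration: defaults, YAML loading, validation, override precedence.

Precedence is defaults < config file < explicit overrides (e.g. from the
command line).  Unknown keys are rejected rather than ignored so that typos
in a config file cannot silently fall back to defaults.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import yaml

from .errors import ConfigError
from .registry import ReferenceTest, default_registry

HueInterval = tuple[float, float]


@dataclass
class ColourConfig:
    """Hue intervals (degrees on the [0, 360) circle) and saturation gate
    used to classify masked pixels as pink, blue or other."""

    pink_hue: list[HueInterval] = field(
        default_factory=lambda: [(270.0, 360.0), (0.0, 30.0)]
    )
    blue_hue: list[HueInterval] = field(default_factory=lambda: [(180.0, 270.0)])
    saturation_gate: float = 0.15
    n_bins: int = 36


@dataclass
class SegmentationConfig:
    """How the pad foreground is separated from the scanner background.

    channel: "saturation" (default; the white scanner bed is unsaturated)
    or "luminance" (pad darker than the bed).  The threshold itself is
    always recomputed per image (Otsu), never a fixed constant.
    """

    channel: str = "saturation"
    method: str = "otsu"
    foreground_floor: float = 0.01
    min_contrast: float = 0.10


@dataclass
class MorphologyConfig:
    """Disc radius for binary opening/closing, in millimetres (converted to
    pixels via the scan dpi so behaviour is resolution independent)."""

    radius_mm: float = 0.5


@dataclass
class CategoryConfig:
    """Thresholds mapping the continuous percentage onto the three-level
    visual read-out: normal if >= t_normal, abnormal if <= t_abnormal,
    intermediate otherwise (boundaries inclusive toward less disease)."""

    t_normal: float = 90.0
    t_abnormal: float = 10.0


@dataclass
class ScreeningConfig:
    """Proposed screening cut-offs on the percentage output: below the
    autonomic cut-off suggests sudomotor/autonomic dysfunction, below the
    structural cut-off suggests structural small-fibre damage."""

    autonomic_cutoff: float = 90.0
    structural_cutoff: float = 80.0


@dataclass
class RunConfig:
    colour: ColourConfig = field(default_factory=ColourConfig)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    morphology: MorphologyConfig = field(default_factory=MorphologyConfig)
    categories: CategoryConfig = field(default_factory=CategoryConfig)
    screening: ScreeningConfig = field(default_factory=ScreeningConfig)
    registry: dict[str, ReferenceTest] = field(default_factory=default_registry)
    seed: int = 0


_SECTION_TYPES = {
    "colour": ColourConfig,
    "segmentation": SegmentationConfig,
    "morphology": MorphologyConfig,
    "categories": CategoryConfig,
    "screening": ScreeningConfig,
}


def _coerce_intervals(key: str, value: Any) -> list[HueInterval]:
    try:
        out = [(float(lo), float(hi)) for lo, hi in value]
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{key} must be a list of [low, high] pairs") from exc
    return out


def _apply_section(section: Any, prefix: str, data: Mapping[str, Any]) -> None:
    valid = {f.name for f in dataclasses.fields(section)}
    for key, value in data.items():
        if key not in valid:
            raise ConfigError(f"unknown config key '{prefix}.{key}'")
        if key in ("pink_hue", "blue_hue"):
            value = _coerce_intervals(f"{prefix}.{key}", value)
        setattr(section, key, value)


def _apply_registry(cfg: RunConfig, data: Mapping[str, Any]) -> None:
    for measure, entry in data.items():
        if not isinstance(entry, Mapping):
            raise ConfigError(f"registry.{measure} must be a mapping")
        unknown = set(entry) - {"threshold", "direction", "units"}
        if unknown:
            raise ConfigError(
                f"unknown config key 'registry.{measure}.{unknown.pop()}'"
            )
        base = cfg.registry.get(measure)
        cfg.registry[measure] = ReferenceTest(
            measure=measure,
            threshold=float(entry.get("threshold", base.threshold if base else 0.0)),
            direction=str(entry.get("direction", base.direction if base else "below")),
            units=str(entry.get("units", base.units if base else "")),
        )


def _validate_intervals(key: str, intervals: Sequence[HueInterval]) -> None:
    if not intervals:
        raise ConfigError(f"{key} must contain at least one interval")
    for lo, hi in intervals:
        if not (0.0 <= lo < hi <= 360.0):
            raise ConfigError(
                f"invalid hue interval [{lo}, {hi}] in '{key}': need 0 <= low < "
                f"high <= 360"
            )


def validate_config(cfg: RunConfig) -> None:
    """Raise :class:`ConfigError` naming the offending key on any violation."""
    _validate_intervals("colour.pink_hue", cfg.colour.pink_hue)
    _validate_intervals("colour.blue_hue", cfg.colour.blue_hue)
    if not (0.0 <= cfg.colour.saturation_gate <= 1.0):
        raise ConfigError("colour.saturation_gate must be in [0, 1]")
    if cfg.colour.n_bins < 1:
        raise ConfigError("colour.n_bins must be >= 1")
    if cfg.segmentation.channel not in ("saturation", "luminance"):
        raise ConfigError("segmentation.channel must be 'saturation' or 'luminance'")
    if cfg.segmentation.method != "otsu":
        raise ConfigError("segmentation.method must be 'otsu'")
    if not (0.0 < cfg.segmentation.foreground_floor < 1.0):
        raise ConfigError("segmentation.foreground_floor must be in (0, 1)")
    if cfg.morphology.radius_mm <= 0:
        raise ConfigError("morphology.radius_mm must be > 0")
    if not (0.0 <= cfg.categories.t_abnormal < cfg.categories.t_normal <= 100.0):
        raise ConfigError(
            "categories: need 0 <= t_abnormal < t_normal <= 100, got "
            f"t_abnormal={cfg.categories.t_abnormal}, t_normal={cfg.categories.t_normal}"
        )
    for test in cfg.registry.values():
        if test.direction not in ("below", "above"):
            raise ConfigError(f"registry.{test.measure}.direction invalid")


def load_config(
    path: str | Path | None = None,
    overrides: Mapping[str, Any] | None = None,
) -> RunConfig:
    """Build a validated :class:`RunConfig`.

    Parameters
    ----------
    path
        Optional YAML (or JSON, a YAML subset) file.  An empty file yields
        all defaults.
    overrides
        Mapping of dotted keys (``"categories.t_normal"``) to values,
        applied after the file.
    """
    cfg = RunConfig()
    if path is not None:
        try:
            raw = yaml.safe_load(Path(path).read_text()) or {}
        except yaml.YAMLError as exc:
            raise ConfigError(f"cannot parse config file {path}: {exc}") from exc
        if not isinstance(raw, Mapping):
            raise ConfigError(f"config file {path} must contain a mapping")
        for key, value in raw.items():
            if key == "registry":
                _apply_registry(cfg, value or {})
            elif key == "seed":
                cfg.seed = int(value)
            elif key in _SECTION_TYPES:
                _apply_section(getattr(cfg, key), key, value or {})
            else:
                raise ConfigError(f"unknown config key '{key}'")
    for dotted, value in (overrides or {}).items():
        parts = dotted.split(".")
        if len(parts) == 1 and parts[0] == "seed":
            cfg.seed = int(value)
            continue
        if len(parts) != 2 or parts[0] not in _SECTION_TYPES:
            raise ConfigError(f"unknown config key '{dotted}'")
        if parts[0] == "registry":
            raise ConfigError("registry overrides must come from a config file")
        _apply_section(getattr(cfg, parts[0]), parts[0], {parts[1]: value})
    validate_config(cfg)
    return cfg


def config_to_dict(cfg: RunConfig) -> dict[str, Any]:
    """Plain-dict echo of the effective configuration (for reproducibility
    metadata written next to pipeline outputs)."""
    out: dict[str, Any] = {}
    for name in _SECTION_TYPES:
        section = getattr(cfg, name)
        out[name] = {
            f.name: getattr(section, f.name) for f in dataclasses.fields(section)
        }
    out["colour"]["pink_hue"] = [list(p) for p in cfg.colour.pink_hue]
    out["colour"]["blue_hue"] = [list(p) for p in cfg.colour.blue_hue]
    out["registry"] = {
        name: {"threshold": t.threshold, "direction": t.direction, "units": t.units}
        for name, t in cfg.registry.items()
    }
    out["seed"] = cfg.seed
    return out


def dump_effective_config(cfg: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config_to_dict(cfg), sort_keys=True))
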