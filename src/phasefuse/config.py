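"""Run configuration: YAML parsing with strict key checking.

Defaults mirror the method's standard operating point: peak-height gate
``H > 0.03``, scale sweep over [0.1, 1.0] with step 0.02, edge-variant
preprocessing, similarity-bounds gating. Unknown keys are rejected so a
typo cannot silently fall back to a default.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields

import yaml

from .errors import ConfigError
from .fourier_mellin import ValidityBounds
from .multiscale import ScaleSweepConfig

_VARIANTS = ("gray", "edge")


@dataclass(frozen=True)
class RunConfig:
    """Effective configuration of a phasefuse run (fully serializable)."""

    variant: str = "edge"
    filter_blue: bool = False
    blue_delta: float = 0.05
    crop_pad: int = 0
    scale_min: float = 0.1
    scale_max: float = 1.0
    step: float = 0.02
    h_threshold: float = 0.03
    bound_scale_min: float = 0.5
    bound_scale_max: float = 2.0
    bound_rot_max_deg: float = 30.0
    bound_shift_max_frac: float = 0.5
    window: bool = True
    subpixel: bool = False
    integration: str = "union"
    flu_threshold: float | None = None
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self):
        if self.variant not in _VARIANTS:
            raise ConfigError(f"variant must be one of {_VARIANTS}")
        if not 0.0 < self.h_threshold < 1.0:
            raise ConfigError("h_threshold must lie in (0, 1)")

    def sweep_config(self) -> ScaleSweepConfig:
        return ScaleSweepConfig(
            scale_min=self.scale_min, scale_max=self.scale_max, step=self.step,
            variant=self.variant, filter_blue=self.filter_blue,
            h_threshold=self.h_threshold,
            bounds=ValidityBounds(scale_min=self.bound_scale_min,
                                  scale_max=self.bound_scale_max,
                                  rot_max_deg=self.bound_rot_max_deg,
                                  shift_max_frac=self.bound_shift_max_frac),
            window=self.window, subpixel=self.subpixel,
            integration=self.integration, flu_threshold=self.flu_threshold)

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path) -> RunConfig:
    """Parse a YAML config file; missing keys take defaults, unknown keys fail.

    An empty file yields the all-defaults configuration.
    """
    try:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    except OSError as exc:
        raise ConfigError(f"cannot read {path}: {exc}") from exc
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    known = {f.name for f in fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"{path}: unknown keys {sorted(unknown)}")
    try:
        return RunConfig(**raw)
    except TypeError as exc:
        raise ConfigError(f"{path}: {exc}") from exc


def dump_config(cfg: RunConfig, path) -> None:
    """Write the effective configuration next to a run's outputs."""
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)
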