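"""Run configuration: defaults, validation, YAML round-trip."""

from __future__ import annotations

from dataclasses import asdict, dataclass, replace
from pathlib import Path

import yaml

from .errors import ConfigError
from .synthetic import OBSERVATION_DAYS

__all__ = ["RunConfig"]


@dataclass(frozen=True)
class RunConfig:
    """Knobs of a batch screening run.

    ``analysis_day`` selects which day's images feed the health
    classification (day 6 by default — the day clearance best separates
    live from dead follicles while antrum formation is still pending).
    """

    threshold_method: str = "otsu"
    threshold_override: float | None = None
    invert: bool = False
    truncation_margin_px: float = 3.0
    cutoff_epsilon: float = 1e-6
    illumination_cv_max: float = 0.10
    analysis_day: int = 6
    seed: int = 0
    output_dir: str = "."

    def __post_init__(self) -> None:
        if self.threshold_method != "otsu":
            raise ConfigError(f"unknown threshold method: {self.threshold_method!r}")
        if self.truncation_margin_px <= 0:
            raise ConfigError("truncation_margin_px must be > 0")
        if self.cutoff_epsilon <= 0:
            raise ConfigError("cutoff_epsilon must be > 0")
        if self.illumination_cv_max <= 0:
            raise ConfigError("illumination_cv_max must be > 0")
        if self.analysis_day not in OBSERVATION_DAYS:
            raise ConfigError(
                f"analysis_day must be one of {OBSERVATION_DAYS}, got {self.analysis_day}"
            )

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"config file {path} must hold a mapping")
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        try:
            return cls(**data)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def with_overrides(self, **overrides) -> "RunConfig":
        return replace(self, **{k: v for k, v in overrides.items() if v is not None})
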