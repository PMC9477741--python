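"""Run configuration: defaults, YAML loading, strict key validation.

The configuration is a small tree of dataclasses. Every analysis-facing
threshold lives here so a run is fully described by one file: the arrest
threshold (3 µm/min, the conventional cutoff below which an instantaneous
step counts as arrested), the minimum track duration, MSD truncation, the
spot/wavy classification thresholds and optional per-regime simulation
overrides. Unknown keys are rejected rather than ignored, so typos fail
loudly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .model import AcquisitionParams

__all__ = [
    "ConfigError",
    "MetricsConfig",
    "ClassificationConfig",
    "PipelineConfig",
    "RunConfig",
    "load_config",
]


class ConfigError(ValueError):
    """Raised for unknown keys or type mismatches in a config file."""


@dataclass
class MetricsConfig:
    arrest_threshold: float = 3.0  # µm/min; steps strictly below count as arrested
    min_track_duration: float = 10.0  # minutes
    msd_max_lag_fraction: float = 0.5  # fraction of (n_points - 1)
    msd_min_tracks: int = 5  # cohort-MSD lags with fewer tracks are truncated


@dataclass
class ClassificationConfig:
    d_min: float = 10.0  # µm net displacement below which a track is a "spot"
    cell_arrest_cutoff: float = 80.0  # percent; per-cell arrested criterion


@dataclass
class PipelineConfig:
    drift_correction: bool = True
    max_gap: int = 1  # frames of missing data tolerated without splitting


@dataclass
class RunConfig:
    acquisition: AcquisitionParams = field(default_factory=AcquisitionParams)
    metrics: MetricsConfig = field(default_factory=MetricsConfig)
    classification: ClassificationConfig = field(default_factory=ClassificationConfig)
    pipeline: PipelineConfig = field(default_factory=PipelineConfig)
    #: per-regime simulation parameter overrides, e.g. {"wt_villus_steady": {"v_run": 8.0}}
    simulation: dict[str, dict[str, float]] = field(default_factory=dict)


_SECTIONS = {
    "acquisition": AcquisitionParams,
    "metrics": MetricsConfig,
    "classification": ClassificationConfig,
    "pipeline": PipelineConfig,
}


def _build_section(cls, data: dict[str, Any], section: str):
    valid = {f.name: f.type for f in dataclasses.fields(cls)}
    unknown = set(data) - set(valid)
    if unknown:
        raise ConfigError(
            f"unknown key(s) {sorted(unknown)} in section {section!r}; "
            f"valid keys: {sorted(valid)}"
        )
    kwargs = {}
    for key, value in data.items():
        default = getattr(cls(), key)
        if isinstance(default, bool):
            if not isinstance(value, bool):
                raise ConfigError(f"{section}.{key} must be a boolean, got {value!r}")
        elif isinstance(default, int) and not isinstance(default, bool):
            if not isinstance(value, int) or isinstance(value, bool):
                raise ConfigError(f"{section}.{key} must be an integer, got {value!r}")
        elif isinstance(default, float):
            if not isinstance(value, (int, float)) or isinstance(value, bool):
                raise ConfigError(f"{section}.{key} must be a number, got {value!r}")
            value = float(value)
        kwargs[key] = value
    return cls(**kwargs)


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load a YAML run configuration, filling defaults.

    An empty or absent file yields all defaults (arrest threshold 3 µm/min,
    minimum duration 10 min, drift correction on). Unknown sections or keys
    raise :class:`ConfigError` listing the valid alternatives.
    """
    if path is None:
        return RunConfig()
    raw = Path(path).read_text(encoding="utf-8")
    data = yaml.safe_load(raw)
    if data is None:
        return RunConfig()
    if not isinstance(data, dict):
        raise ConfigError(f"config root must be a mapping, got {type(data).__name__}")
    unknown = set(data) - set(_SECTIONS) - {"simulation"}
    if unknown:
        raise ConfigError(
            f"unknown section(s) {sorted(unknown)}; valid sections: "
            f"{sorted(_SECTIONS) + ['simulation']}"
        )
    kwargs: dict[str, Any] = {}
    for name, cls in _SECTIONS.items():
        section = data.get(name, {})
        if not isinstance(section, dict):
            raise ConfigError(f"section {name!r} must be a mapping")
        kwargs[name] = _build_section(cls, section, name)
    sim = data.get("simulation", {})
    if not isinstance(sim, dict) or any(not isinstance(v, dict) for v in sim.values()):
        raise ConfigError("section 'simulation' must map regime names to parameter mappings")
    # regime names / parameter keys are validated against RegimeParams at use time
    kwargs["simulation"] = {str(k): dict(v) for k, v in sim.items()}
    return RunConfig(**kwargs)
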