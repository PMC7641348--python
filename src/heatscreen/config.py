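"""Pipeline configuration: defaults, YAML loading, and validation.

The configuration gathers every fixed constant of the analysis — the
vulnerability threshold (75th percentile), the heat-index day cutoff
(91 °F), the heat-wave quantile (0.95) and minimum duration (2 days), the
three periods (historical 1950–1999, current 2006–2025, projected
2040–2059) and the Apr 1 – Oct 31 season — plus file paths, stage gating,
the seed, and synthetic-scenario overrides.  Unknown keys are rejected so
typos fail loudly, and range violations name the offending field.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from .synthetic_data import SyntheticConfig

ALL_STAGES = ("vulnerability", "exposure", "overlay", "interventions")


@dataclass
class PipelineConfig:
    # inputs; when a path is None the synthetic generator supplies that table
    ces_path: str | None = None
    hhai_path: str | None = None
    svi_path: str | None = None
    climate_path: str | None = None
    projects_path: str | None = None
    rules_path: str | None = None

    # analysis constants
    vulnerability_threshold: float = 75.0
    hi_threshold_f: float = 91.0
    heatwave_quantile: float = 0.95
    min_duration: int = 2
    historical: tuple[int, int] = (1950, 1999)
    current: tuple[int, int] = (2006, 2025)
    projected: tuple[int, int] = (2040, 2059)
    season_start: tuple[int, int] = (4, 1)
    season_end: tuple[int, int] = (10, 31)
    bin_width: float = 2.5
    overlay_metric: str = "daytime_hw"

    # orchestration
    stages: tuple[str, ...] = ALL_STAGES
    seed: int = 0
    outdir: str = "heatscreen_out"
    n_climate_tracts: int = 60  # synthetic exposure subsample; full table is impractical
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)

    def validate(self) -> "PipelineConfig":
        if not 0 <= self.vulnerability_threshold <= 100:
            raise ValueError("vulnerability_threshold must lie in [0, 100]")
        if not 0 < self.heatwave_quantile < 1:
            raise ValueError("heatwave_quantile must lie in (0, 1)")
        if self.min_duration < 1:
            raise ValueError("min_duration must be >= 1")
        if self.hi_threshold_f <= 0:
            raise ValueError("hi_threshold_f must be positive")
        for name in ("historical", "current", "projected"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"period {name} is reversed: {lo} > {hi}")
        if not (self.historical[1] < self.current[0] <= self.current[1] < self.projected[0]):
            raise ValueError("periods must be ordered and non-overlapping: "
                             "historical < current < projected")
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        self.synthetic.validate()
        return self

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        return d


_PIPELINE_FIELDS = {f.name for f in dataclasses.fields(PipelineConfig)}
_SYNTH_FIELDS = {f.name for f in dataclasses.fields(SyntheticConfig)}
_TUPLE_FIELDS = ("historical", "current", "projected", "season_start", "season_end", "stages")


def config_from_dict(data: Mapping[str, Any] | None) -> PipelineConfig:
    """Build a validated config from a plain mapping, applying defaults."""
    data = dict(data or {})
    synth_raw = data.pop("synthetic", {}) or {}
    unknown = set(data) - _PIPELINE_FIELDS
    if unknown:
        raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
    unknown_s = set(synth_raw) - _SYNTH_FIELDS
    if unknown_s:
        raise ValueError(f"unknown synthetic keys: {sorted(unknown_s)}")
    for key in _TUPLE_FIELDS:
        if key in data and data[key] is not None:
            data[key] = tuple(data[key])
    for key in ("models", "historical", "current", "projected"):
        if key in synth_raw and synth_raw[key] is not None:
            synth_raw[key] = tuple(synth_raw[key])
    cfg = PipelineConfig(**data, synthetic=SyntheticConfig(**synth_raw))
    return cfg.validate()


def load_config(path) -> PipelineConfig:
    """Load a YAML configuration file; an empty file yields all defaults."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return config_from_dict(raw)


def save_config(config: PipelineConfig, path) -> None:
    """Write the fully resolved configuration back to YAML (round-trips)."""
    payload = config.to_dict()
    for key in _TUPLE_FIELDS:
        payload[key] = list(payload[key])
    for key in ("models", "historical", "current", "projected"):
        payload["synthetic"][key] = list(payload["synthetic"][key])
    payload["synthetic"]["regions"] = dict(payload["synthetic"]["regions"])
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))
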