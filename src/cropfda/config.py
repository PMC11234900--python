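"""Pipeline configuration: one YAML document driving every stage.

The configuration is deliberately flat and explicit — units are labels taken
from the file, never inferred from data.  ``strawberry_defaults`` and
``tomato_defaults`` encode the two study setups: a 60-day lag with yields in
packages/day (250 g per package), and an 80-day lag with yields in kg/day.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    sensor_paths: dict[str, str] = field(default_factory=dict)
    yield_path: str = ""
    yield_units: str = "kg/day"
    sensor_units: dict[str, str] = field(default_factory=dict)
    lag_days: int = 80
    season_origin: str = "2020-10-01"
    ma_window_days: int = 7
    ma_min_present: int = 4
    max_gap_hours: int = 24
    n_basis_s: int = 10
    n_basis_t: int = 10
    spline_order: int = 4
    t_domain: list = field(default_factory=lambda: [0.0, 365.0])
    rho: str | float = "gcv"
    lambda_s_grid: list = field(
        default_factory=lambda: [float(v) for v in np.logspace(-4, 4, 9)]
    )
    lambda_t_grid: list = field(
        default_factory=lambda: [float(v) for v in np.logspace(-4, 4, 9)]
    )
    criterion: str = "gcv"
    seasonal_intercept: bool = True
    gap: int = 6
    min_train: int = 50
    reselect_every: int = 30
    cadence_minutes: int = 1
    seed: int = 0

    def validate(self) -> None:
        if self.lag_days < 1:
            raise ConfigError(f"lag_days must be >= 1, got {self.lag_days}")
        if self.ma_window_days < 1:
            raise ConfigError("ma_window_days must be >= 1")
        if not (1 <= self.ma_min_present <= self.ma_window_days):
            raise ConfigError(
                "ma_min_present must be in [1, ma_window_days]"
            )
        if self.n_basis_s < self.spline_order or self.n_basis_t < 1:
            raise ConfigError("basis sizes incompatible with spline order")
        if self.criterion not in ("gcv", "gic"):
            raise ConfigError(f"unknown criterion {self.criterion!r}")
        if self.gap < 0 or self.min_train < 2:
            raise ConfigError("invalid protocol settings")
        if self.cadence_minutes < 1:
            raise ConfigError("cadence_minutes must be >= 1")
        if len(self.t_domain) != 2 or not self.t_domain[1] > self.t_domain[0]:
            raise ConfigError(f"bad t_domain {self.t_domain}")
        if isinstance(self.rho, str) and self.rho != "gcv":
            raise ConfigError(f"rho must be a number or 'gcv', got {self.rho!r}")


_KNOWN_KEYS = set(PipelineConfig.__dataclass_fields__)


def load_config(path) -> PipelineConfig:
    """Load and validate a YAML config; unknown keys are an error."""
    doc = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(doc, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    unknown = set(doc) - _KNOWN_KEYS
    if unknown:
        raise ConfigError(f"{path}: unknown config keys {sorted(unknown)}")
    cfg = PipelineConfig(**doc)
    cfg.validate()
    return cfg


def dump_config(cfg: PipelineConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(asdict(cfg), sort_keys=False))


def strawberry_defaults() -> PipelineConfig:
    """60-day lag, December–June harvests, yields in 250 g packages/day."""
    cfg = PipelineConfig(
        lag_days=60,
        yield_units="packages/day (250 g per package)",
        season_origin="2020-12-01",
    )
    cfg.validate()
    return cfg


def tomato_defaults() -> PipelineConfig:
    """80-day lag, October–July harvests pooled over years, yields in kg/day."""
    cfg = PipelineConfig(
        lag_days=80,
        yield_units="kg/day",
        season_origin="2020-10-01",
    )
    cfg.validate()
    return cfg
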