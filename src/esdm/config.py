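"""Run configuration: one human-readable YAML file, validated on load.

Every workflow default is recorded here so that deviations from the standard
protocol (5000 pseudo-absences, 5-fold × 10-repetition cross-validation,
TSS > 0.80 / AUC > 0.85 gates, TSS-proportional ensemble weights) are visible
as config diffs.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .env_stack import DEFAULT_CELL_SIZE, DEFAULT_EXTENT

__all__ = ["RunConfig", "ConfigError"]


class ConfigError(ValueError):
    """Malformed run configuration."""


@dataclass
class RunConfig:
    # paths
    presences_csv: str = "presences.csv"
    layer_manifest: str = "manifest.yaml"
    output_dir: str = "esdm_run"
    # grid extent
    lon_min: float = DEFAULT_EXTENT[0]
    lon_max: float = DEFAULT_EXTENT[1]
    lat_min: float = DEFAULT_EXTENT[2]
    lat_max: float = DEFAULT_EXTENT[3]
    cell_size: float = DEFAULT_CELL_SIZE
    # occurrence handling
    thinning: bool = True
    # pseudo-absences
    n_pseudo_absences: int = 5000
    pa_strategy: str = "sre"            # 'sre' (envelope exclusion) or 'random'
    envelope_quantile: float = 0.025
    # cross-validation
    cv_folds: int = 5
    cv_repetitions: int = 10
    # retention gates (strict >)
    tss_gate: float = 0.80
    auc_gate: float = 0.85
    # ensemble
    ensemble_metric: str = "tss"
    # scenarios: 'default' (the eight RCP × horizon shifts) or explicit list
    scenarios: str | list = "default"
    # synthetic generator
    n_presences: int = 82
    smoothness: float = 6.0
    # importance
    n_permutations: int = 10
    # algorithms and hyperparameter overrides
    algorithms: list = field(default_factory=list)  # empty = all ten
    hyperparameters: dict = field(default_factory=dict)
    # master seed, fanned out to every stochastic stage
    seed: int = 0

    def __post_init__(self):
        self.validate()

    def validate(self):
        checks = [
            (self.cell_size > 0, "cell_size must be > 0"),
            (self.lon_max > self.lon_min, "lon_max must exceed lon_min"),
            (self.lat_max > self.lat_min, "lat_max must exceed lat_min"),
            (self.n_pseudo_absences >= 1, "n_pseudo_absences must be >= 1"),
            (0 <= self.envelope_quantile < 0.5, "envelope_quantile must be in [0, 0.5)"),
            (self.cv_folds >= 2, "cv_folds must be >= 2"),
            (self.cv_repetitions >= 1, "cv_repetitions must be >= 1"),
            (-1 <= self.tss_gate <= 1, "tss_gate must be in [-1, 1]"),
            (0 <= self.auc_gate <= 1, "auc_gate must be in [0, 1]"),
            (self.pa_strategy in ("sre", "random"), "pa_strategy must be 'sre' or 'random'"),
            (self.ensemble_metric in ("tss", "auc"), "ensemble_metric must be 'tss' or 'auc'"),
            (self.n_presences >= 1, "n_presences must be >= 1"),
            (self.smoothness >= 0, "smoothness must be >= 0"),
            (self.n_permutations >= 1, "n_permutations must be >= 1"),
            (int(self.seed) == self.seed, "seed must be an integer"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ConfigError(msg)

    @property
    def grid(self):
        from .env_stack import GridSpec

        return GridSpec(
            lon_min=self.lon_min,
            lon_max=self.lon_max,
            lat_min=self.lat_min,
            lat_max=self.lat_max,
            cell_size=self.cell_size,
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        try:
            raw = yaml.safe_load(Path(path).read_text()) or {}
        except (OSError, yaml.YAMLError) as exc:
            raise ConfigError(f"cannot read config {path!r}: {exc}") from exc
        if not isinstance(raw, dict):
            raise ConfigError(f"config {path!r} must be a mapping")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config field(s): {sorted(unknown)}")
        try:
            return cls(**raw)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))
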