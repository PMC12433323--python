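"""Pipeline configuration: schema, defaults, YAML loading and hashing.

A single YAML (or JSON — YAML is a superset) document configures every
stage.  Defaults mirror the analysis settings of the study design this
package implements: 6 cubic B-spline basis functions, AUC window days
30-41 with 10,000 iterations, pooled Student t-test at alpha 0.05, and
top-3 hot-spot averaging over 500x500 µm regions.  Simulation seeds are
always explicit — there is no silent default seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import yaml

from .errors import ConfigError
from .geometry import CALIPER_CONVENTIONS
from .cohort_stats import T_VARIANTS


@dataclass(frozen=True)
class SplineConfig:
    n_basis: int = 6
    order: int = 4

    def validate(self) -> None:
        if self.order < 1 or self.n_basis < self.order:
            raise ConfigError(
                f"spline needs n_basis >= order >= 1, got n_basis={self.n_basis}, "
                f"order={self.order}"
            )


@dataclass(frozen=True)
class AUCConfig:
    window: tuple[float, float] = (30.0, 41.0)
    n_iter: int = 10_000
    seed: int | None = None

    def validate(self) -> None:
        if len(self.window) != 2 or not self.window[0] < self.window[1]:
            raise ConfigError(f"auc window must be (start, end), got {self.window}")
        if self.n_iter < 1:
            raise ConfigError(f"auc n_iter must be >= 1, got {self.n_iter}")
        if self.seed is not None and not isinstance(self.seed, int):
            raise ConfigError(f"auc seed must be an integer, got {self.seed!r}")


@dataclass(frozen=True)
class StatsConfig:
    variant: str = "student_pooled"
    alpha: float = 0.05

    def validate(self) -> None:
        if self.variant not in T_VARIANTS:
            raise ConfigError(
                f"t-test variant must be one of {T_VARIANTS}, got {self.variant!r}"
            )
        if not 0 < self.alpha < 1:
            raise ConfigError(f"alpha must be in (0, 1), got {self.alpha}")


@dataclass(frozen=True)
class ApoptosisConfig:
    region_dims_um: tuple[float, float] = (500.0, 500.0)
    top_k: int = 3
    include_partial_regions: bool = False

    def validate(self) -> None:
        if min(self.region_dims_um) <= 0:
            raise ConfigError(f"region dims must be positive, got {self.region_dims_um}")
        if self.top_k < 1:
            raise ConfigError(f"top_k must be >= 1, got {self.top_k}")


@dataclass(frozen=True)
class PipelineConfig:
    """Validated configuration for the whole pipeline."""

    caliper_convention: str = "semi_axes"
    spline: SplineConfig = field(default_factory=SplineConfig)
    auc: AUCConfig = field(default_factory=AUCConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)
    apoptosis: ApoptosisConfig = field(default_factory=ApoptosisConfig)

    def validate(self) -> "PipelineConfig":
        if self.caliper_convention not in CALIPER_CONVENTIONS:
            raise ConfigError(
                f"caliper_convention must be one of {CALIPER_CONVENTIONS}, "
                f"got {self.caliper_convention!r}"
            )
        for section in (self.spline, self.auc, self.stats, self.apoptosis):
            section.validate()
        return self

    def to_dict(self) -> dict:
        return asdict(self)

    @property
    def hash(self) -> str:
        """Short stable digest of the full configuration (provenance)."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw or {})
        known = {"caliper_convention", "spline", "auc", "stats", "apoptosis"}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")

        def build(section_cls, key):
            sub = raw.get(key, {})
            if not isinstance(sub, dict):
                raise ConfigError(f"config section {key!r} must be a mapping")
            fields = {f for f in section_cls.__dataclass_fields__}
            bad = set(sub) - fields
            if bad:
                raise ConfigError(f"unknown keys in {key!r}: {sorted(bad)}")
            sub = {
                k: tuple(v) if isinstance(v, list) else v for k, v in sub.items()
            }
            return section_cls(**sub)

        cfg = cls(
            caliper_convention=raw.get("caliper_convention", "semi_axes"),
            spline=build(SplineConfig, "spline"),
            auc=build(AUCConfig, "auc"),
            stats=build(StatsConfig, "stats"),
            apoptosis=build(ApoptosisConfig, "apoptosis"),
        )
        return cfg.validate()

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        if raw is not None and not isinstance(raw, dict):
            raise ConfigError(f"config file {path} must contain a mapping")
        return cls.from_dict(raw or {})
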