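"""Run configuration: one YAML/JSON file drives the whole pipeline.

The file holds one section per stage (``simulate``, ``localize``, ``link``,
``diffusion``), a ``conditions`` list, a single ``seed`` and an output
directory.  Unknown keys anywhere are rejected so a typo cannot silently
fall back to a default.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .detect import LocalizeParams
from .simulate import SptSimConfig
from .tracking import LinkParams


class ConfigError(ValueError):
    """Invalid or malformed run configuration (CLI exit code 2)."""


@dataclass
class DiffusionParams:
    d_threshold: float = 0.3   # um^2/s


@dataclass
class ConditionSpec:
    label: str
    f_bound: float
    n_cells: int = 3

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ConfigError("n_cells must be >= 1")
        if not (0.0 <= self.f_bound <= 1.0):
            raise ConfigError("f_bound must lie in [0, 1]")


@dataclass
class RunConfig:
    seed: int = 0
    outdir: str = "sptquant_run"
    save_movies: bool = False
    simulate: dict = field(default_factory=dict)    # SptSimConfig overrides
    localize: dict = field(default_factory=dict)    # LocalizeParams overrides
    link: dict = field(default_factory=dict)        # LinkParams overrides
    diffusion: dict = field(default_factory=dict)   # DiffusionParams overrides
    conditions: list = field(default_factory=lambda: [
        ConditionSpec(label="untreated", f_bound=0.2),
        ConditionSpec(label="damage", f_bound=0.5),
    ])

    def __post_init__(self) -> None:
        _check_keys(self.simulate, SptSimConfig, "simulate",
                    forbidden={"nucleus_mask", "seed", "f_bound"})
        _check_keys(self.localize, LocalizeParams, "localize")
        _check_keys(self.link, LinkParams, "link")
        _check_keys(self.diffusion, DiffusionParams, "diffusion")
        self.conditions = [
            c if isinstance(c, ConditionSpec) else ConditionSpec(**c)
            for c in self.conditions
        ]
        if len({c.label for c in self.conditions}) != len(self.conditions):
            raise ConfigError("condition labels must be unique")

    def localize_params(self) -> LocalizeParams:
        kw = dict(self.localize)
        kw.setdefault("pixel_size",
                      self.simulate.get("pixel_size",
                                        SptSimConfig.pixel_size))
        return LocalizeParams(**kw)

    def link_params(self) -> LinkParams:
        return LinkParams(**self.link)

    def diffusion_params(self) -> DiffusionParams:
        return DiffusionParams(**self.diffusion)

    def frame_interval(self) -> float:
        return self.simulate.get("frame_interval", SptSimConfig.frame_interval)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["conditions"] = [dataclasses.asdict(c) for c in self.conditions]
        return d


def _check_keys(section: dict, cls, name: str, forbidden: set | None = None) -> None:
    if not isinstance(section, dict):
        raise ConfigError(f"section {name!r} must be a mapping")
    allowed = {f.name for f in dataclasses.fields(cls)} - (forbidden or set())
    unknown = set(section) - allowed
    if unknown:
        raise ConfigError(
            f"unknown key(s) in section {name!r}: {sorted(unknown)}")


def load_run_config(path) -> RunConfig:
    """Load and validate a YAML (or JSON; YAML is a superset) run config."""
    try:
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
    except (OSError, yaml.YAMLError) as exc:
        raise ConfigError(f"cannot read config {path}: {exc}") from exc
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    allowed = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - allowed
    if unknown:
        raise ConfigError(f"{path}: unknown top-level key(s): {sorted(unknown)}")
    try:
        return RunConfig(**data)
    except (TypeError, ValueError) as exc:
        if isinstance(exc, ConfigError):
            raise
        raise ConfigError(f"{path}: {exc}") from exc


def save_run_config(config: RunConfig, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
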