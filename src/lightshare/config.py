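"""Run configuration for the command-line pipeline.

A run config is a YAML file with three blocks (all optional, defaults
shown by ``RunConfig.default()``)::

    paths:
      genotype_dir: null        # directory of cultivar YAMLs; null = shipped
      output_dir: results
    experiment:
      stages: [300, 600, 1240, 1560]
      genotypes: [China, US13, Lucy, James, AOPH10, "886/01"]
      replicates: 8
      seed: 1
      plot_x: 0.51
      plot_y: 0.51
    light:
      n_zenith: 5
      n_azimuth: 4
      rays_per_sector: 100000
    flags:
      export_meshes: false
      plots: false

Unknown keys anywhere in the file are rejected.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig", "load_config"]


class ConfigError(ValueError):
    pass


_SCHEMA = {
    "paths": {"genotype_dir", "output_dir"},
    "experiment": {
        "stages", "genotypes", "replicates", "seed", "plot_x", "plot_y",
        "inter_row", "density_wheat", "density_pea",
    },
    "light": {"n_zenith", "n_azimuth", "rays_per_sector"},
    "flags": {"export_meshes", "plots"},
}


@dataclass
class RunConfig:
    genotype_dir: Path | None = None
    output_dir: Path = Path("results")
    stages: list[float] = field(default_factory=lambda: [300.0, 600.0, 1240.0, 1560.0])
    genotypes: list[str] = field(
        default_factory=lambda: ["China", "US13", "Lucy", "James", "AOPH10", "886/01"]
    )
    replicates: int = 8
    seed: int = 1
    plot_x: float = 0.51
    plot_y: float = 0.51
    inter_row: float = 0.17
    density_wheat: float = 125.0
    density_pea: float = 45.0
    n_zenith: int = 5
    n_azimuth: int = 4
    rays_per_sector: int = 100_000
    export_meshes: bool = False
    plots: bool = False

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ConfigError("experiment.replicates must be >= 1")
        if self.rays_per_sector < 1:
            raise ConfigError("light.rays_per_sector must be >= 1")
        if not self.stages:
            raise ConfigError("experiment.stages must be non-empty")
        if not self.genotypes:
            raise ConfigError("experiment.genotypes must be non-empty")

    @classmethod
    def default(cls) -> "RunConfig":
        return cls()


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    p = Path(path)
    if not p.exists():
        raise ConfigError(f"config file not found: {p}")
    with open(p) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{p}: top level must be a mapping")
    unknown_blocks = set(raw) - set(_SCHEMA)
    if unknown_blocks:
        raise ConfigError(f"{p}: unknown config blocks {sorted(unknown_blocks)}")
    kwargs: dict = {}
    for block, keys in _SCHEMA.items():
        sub = raw.get(block) or {}
        if not isinstance(sub, dict):
            raise ConfigError(f"{p}: block {block!r} must be a mapping")
        unknown = set(sub) - keys
        if unknown:
            raise ConfigError(f"{p}: unknown keys in {block!r}: {sorted(unknown)}")
        kwargs.update(sub)
    if kwargs.get("genotype_dir"):
        kwargs["genotype_dir"] = Path(kwargs["genotype_dir"])
    if "output_dir" in kwargs:
        kwargs["output_dir"] = Path(kwargs["output_dir"])
    return RunConfig(**kwargs)
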