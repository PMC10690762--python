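"""Shared run configuration, loaded from a YAML file.

Holds the knobs that cut across modules: survey interval, solver
tolerances and caps, multi-start count, Monte Carlo retry policy,
species-map path, and projection horizon.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import yaml

from .abundance import SpeciesGroupMap

__all__ = ["RunConfig", "load_species_map"]


@dataclass(frozen=True)
class RunConfig:
    survey_interval: int = 5
    fixed_point_tol: float = 1e-12
    max_iterations: int = 1_000_000
    n_starts: int = 16
    mc_tol: float = 1e-10
    mc_max_redraws: int = 100
    species_map_path: str | None = None
    horizon_year: int = 2119

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def load_species_map(path: str | None) -> SpeciesGroupMap:
    """Load a ``{group: [species, ...]}`` YAML map, or the built-in default."""
    if path is None:
        return SpeciesGroupMap.default()
    with open(path, encoding="utf-8") as fh:
        groups = yaml.safe_load(fh)
    return SpeciesGroupMap.from_group_lists(groups)
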