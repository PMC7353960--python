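"""Declarative run configuration.

A :class:`VettingConfig` is the full recipe for one vetting run: the
landscape, the number of agents, the candidate hypothesis grid, the
iteration count, the seed and the overlap method. The revision step of the
workflow is an edit-and-rerun loop over this file, so the config is plain
YAML and validation reports field paths.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple, Union

import yaml

from .landscape import LAYOUTS, LandscapeConfig
from .settlement import HypothesisSpec, default_hypothesis_grid
from .vetting import OVERLAP_METHODS

__all__ = ["VettingConfig", "ConfigError"]


class ConfigError(ValueError):
    """Invalid configuration; the message lists offending field paths."""


@dataclass
class VettingConfig:
    """Parameters of one hypothesis-vetting run.

    Defaults reproduce the bundled two-habitat settlement example: a 50x50
    blocked landscape (half Habitat A), 150 agents, one null model, five
    habitat-preference strengths and five conspecific-attraction strengths
    (11 parametrizations), 1000 iterations each.
    """

    n_rows: int = 50
    n_cols: int = 50
    prop_a: float = 0.5
    layout: str = "blocked"
    n_agents: int = 150
    omega_values: Tuple[float, ...] = (1.5, 2.0, 4.0, 8.0, 16.0)
    s_values: Tuple[float, ...] = (0.25, 0.5, 1.0, 2.0, 4.0)
    include_null: bool = True
    n_iter: int = 1000
    base_seed: int = 2020
    regenerate_landscape: bool = True
    overlap_method: str = "range"
    alpha: float = 0.05
    spatial_metrics: bool = True

    # -- validation ----------------------------------------------------------

    def validate(self) -> None:
        errors: List[str] = []
        if self.n_rows < 1:
            errors.append(f"n_rows: must be >= 1, got {self.n_rows}")
        if self.n_cols < 1:
            errors.append(f"n_cols: must be >= 1, got {self.n_cols}")
        if not 0.0 <= self.prop_a <= 1.0:
            errors.append(f"prop_a: must lie in [0, 1], got {self.prop_a}")
        if self.layout not in LAYOUTS:
            errors.append(f"layout: must be one of {LAYOUTS}, got {self.layout!r}")
        n_cells = max(self.n_rows, 1) * max(self.n_cols, 1)
        if not 1 <= self.n_agents <= n_cells:
            errors.append(
                f"n_agents: must lie in [1, {n_cells}] for a "
                f"{self.n_rows}x{self.n_cols} grid, got {self.n_agents}"
            )
        for i, w in enumerate(self.omega_values):
            if w < 1:
                errors.append(f"omega_values[{i}]: must be >= 1, got {w}")
        for i, s in enumerate(self.s_values):
            if s < 0:
                errors.append(f"s_values[{i}]: must be >= 0, got {s}")
        if self.n_parametrizations < 2:
            errors.append(
                "hypothesis grid: at least two parametrizations are required "
                f"to compare, got {self.n_parametrizations}"
            )
        if self.n_iter < 2:
            errors.append(f"n_iter: must be >= 2, got {self.n_iter}")
        if self.overlap_method not in OVERLAP_METHODS:
            errors.append(
                f"overlap_method: must be one of {OVERLAP_METHODS}, "
                f"got {self.overlap_method!r}"
            )
        if not 0.0 < self.alpha < 1.0:
            errors.append(f"alpha: must lie in (0, 1), got {self.alpha}")
        if errors:
            raise ConfigError("invalid config:\n  " + "\n  ".join(errors))

    # -- derived objects -----------------------------------------------------

    @property
    def n_parametrizations(self) -> int:
        return int(self.include_null) + len(self.omega_values) + len(self.s_values)

    def landscape_config(self) -> LandscapeConfig:
        return LandscapeConfig(
            n_rows=self.n_rows,
            n_cols=self.n_cols,
            prop_a=self.prop_a,
            layout=self.layout,
        )

    def hypothesis_specs(self) -> List[HypothesisSpec]:
        return default_hypothesis_grid(
            omega_values=self.omega_values,
            s_values=self.s_values,
            include_null=self.include_null,
        )

    # -- YAML round trip -------------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["omega_values"] = list(self.omega_values)
        d["s_values"] = list(self.s_values)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "VettingConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config fields: {sorted(unknown)}")
        d = dict(d)
        for key in ("omega_values", "s_values"):
            if key in d:
                d[key] = tuple(float(v) for v in d[key])
        return cls(**d)

    def to_yaml(self, path: Union[str, Path]) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "VettingConfig":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise ConfigError(f"config file {path} does not contain a mapping")
        return cls.from_dict(data)
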