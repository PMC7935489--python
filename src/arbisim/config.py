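"""Run configuration: YAML loading, validation and defaults.

A run config merges the scaled model parameters, a variant-grid
specification and the passaging settings.  Unknown keys are rejected so a
typo cannot silently fall back to a default.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Any, Optional

import numpy as np
import yaml

from .grid import VariantGrid
from .parameters import ScaledParameters
from .passaging import PassagingConfig

_PARAM_KEYS = {f.name for f in fields(ScaledParameters)}
_PASSAGING_KEYS = {f.name for f in fields(PassagingConfig)}
_GRID_KEYS = {
    "scenario", "phi_min", "phi_max", "phi_step", "theta_min", "theta_max", "theta_step",
}
_TOP_KEYS = {"output", "verbosity"}


@dataclass
class RunConfig:
    """Validated bundle of everything one simulation run needs."""

    params: ScaledParameters = field(default_factory=ScaledParameters)
    grid: VariantGrid = None
    passaging: PassagingConfig = field(default_factory=PassagingConfig)
    output: Optional[str] = None
    verbosity: int = 1

    def __post_init__(self) -> None:
        if self.grid is None:
            self.grid = default_grid("constant-propensity")

    def metadata(self, seed: Optional[int] = None) -> dict:
        """Everything needed to reconstruct this run, as plain scalars."""
        from . import __version__

        meta: dict = {"package_version": __version__}
        for f in fields(ScaledParameters):
            meta[f.name] = getattr(self.params, f.name)
        for f in fields(PassagingConfig):
            v = getattr(self.passaging, f.name)
            meta[f.name] = v.tolist() if isinstance(v, np.ndarray) else v
        meta["n_variants"] = self.grid.n_variants
        meta["scenario"] = self.grid.scenario
        if seed is not None:
            meta["seed"] = seed
        return meta


def default_grid(scenario: str) -> VariantGrid:
    """The two standard study grids.

    constant-propensity: 101 variants, phi 0..0.5 step 0.005;
    communication: 441 variants, phi_max and theta 0..1 step 0.05.
    """
    if scenario == "constant-propensity":
        return VariantGrid.constant_propensity(np.arange(0, 0.5001, 0.005))
    if scenario == "communication":
        return VariantGrid.communication(np.arange(0, 1.0001, 0.05), np.arange(0, 1.0001, 0.05))
    raise ValueError(f"unknown scenario {scenario!r}")


def _grid_from_mapping(spec: dict) -> VariantGrid:
    unknown = set(spec) - _GRID_KEYS
    if unknown:
        raise ValueError(f"unknown grid keys: {sorted(unknown)}")
    scenario = spec.get("scenario", "constant-propensity")
    explicit = set(spec) - {"scenario"}
    if not explicit:
        return default_grid(scenario)
    phi = np.arange(
        spec.get("phi_min", 0.0),
        spec.get("phi_max", 0.5 if scenario == "constant-propensity" else 1.0) + 1e-12,
        spec.get("phi_step", 0.005 if scenario == "constant-propensity" else 0.05),
    )
    if scenario == "constant-propensity":
        return VariantGrid.constant_propensity(phi)
    theta = np.arange(
        spec.get("theta_min", 0.0),
        spec.get("theta_max", 1.0) + 1e-12,
        spec.get("theta_step", 0.05),
    )
    return VariantGrid.communication(phi, theta)


def config_from_mapping(data: dict) -> RunConfig:
    """Build a RunConfig from a plain mapping (e.g. parsed YAML)."""
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValueError("config root must be a mapping")
    allowed = _PARAM_KEYS | _PASSAGING_KEYS | _TOP_KEYS | {"grid"}
    unknown = set(data) - allowed
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")

    def build(cls, keys):
        kwargs = {k: data[k] for k in keys if k in data}
        try:
            return cls(**kwargs)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"invalid configuration: {exc}") from exc

    params = build(ScaledParameters, _PARAM_KEYS)
    passaging = build(PassagingConfig, _PASSAGING_KEYS)
    grid = _grid_from_mapping(data.get("grid") or {})
    return RunConfig(
        params=params,
        grid=grid,
        passaging=passaging,
        output=data.get("output"),
        verbosity=data.get("verbosity", 1),
    )


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration; omitted keys default."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return config_from_mapping(data)
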