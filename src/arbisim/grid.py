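"""Discrete grids of phage strategies with mutation adjacency.

A phage variant is a pair (phi_max, theta): theta is the arbitrium
concentration (in cK units) above which infections become lysogenic with
propensity phi_max; below the threshold infections are lytic.  Variants
with theta = 0 lysogenise with constant propensity phi_max regardless of
the signal, so the constant-propensity (bet-hedging) scenario is the
special case of a grid whose theta axis has the single value 0.

Variants live on a regular product lattice (n_phi x n_theta), flattened
row-major (theta fastest), which is the adjacency the mutation operator
acts on: mutations move burst mass to nearest neighbours along one trait
axis at a time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


def _regular_axis(values: np.ndarray, name: str) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or values.size == 0:
        raise ValueError(f"{name} axis must be a non-empty 1-D array")
    if values.size > 1:
        steps = np.diff(values)
        if np.any(steps <= 0) or not np.allclose(steps, steps[0], rtol=1e-9, atol=1e-12):
            raise ValueError(f"{name} axis must be strictly increasing and regularly spaced")
    return values


@dataclass(frozen=True)
class VariantGrid:
    """Product lattice of phage strategies (phi_max x theta)."""

    phi_axis: np.ndarray
    theta_axis: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "phi_axis", _regular_axis(self.phi_axis, "phi_max"))
        object.__setattr__(self, "theta_axis", _regular_axis(self.theta_axis, "theta"))
        if self.phi_axis.min() < 0 or self.phi_axis.max() > 1:
            raise ValueError("phi_max values must lie in [0, 1]")
        if self.theta_axis.min() < 0:
            raise ValueError("theta values must be non-negative")
        self.phi_axis.setflags(write=False)
        self.theta_axis.setflags(write=False)

    # -- constructors ---------------------------------------------------

    @classmethod
    def constant_propensity(cls, phi_values: np.ndarray) -> "VariantGrid":
        """Bet-hedging grid: constant lysogeny propensities, no communication."""
        return cls(phi_axis=np.asarray(phi_values, dtype=float), theta_axis=np.zeros(1))

    @classmethod
    def communication(cls, phi_max_values: np.ndarray, theta_values: np.ndarray) -> "VariantGrid":
        return cls(
            phi_axis=np.asarray(phi_max_values, dtype=float),
            theta_axis=np.asarray(theta_values, dtype=float),
        )

    @classmethod
    def single(cls, phi_max: float, theta: float = 0.0) -> "VariantGrid":
        return cls(phi_axis=np.array([phi_max]), theta_axis=np.array([theta]))

    @classmethod
    def pair(cls, variant_a: tuple, variant_b: tuple) -> "VariantGrid":
        """Irregular two-variant grid for competition experiments (no mutation)."""
        grid = cls.__new__(cls)
        object.__setattr__(grid, "phi_axis", None)
        object.__setattr__(grid, "theta_axis", None)
        phi = np.array([variant_a[0], variant_b[0]], dtype=float)
        theta = np.array([variant_a[1], variant_b[1]], dtype=float)
        if phi.min() < 0 or phi.max() > 1 or theta.min() < 0:
            raise ValueError("traits out of range")
        object.__setattr__(grid, "_flat", (phi, theta, 2, 1))
        return grid

    # -- flattened views ------------------------------------------------

    @property
    def n_phi(self) -> int:
        return self._flat_arrays()[2]

    @property
    def n_theta(self) -> int:
        return self._flat_arrays()[3]

    @property
    def n_variants(self) -> int:
        phi, _, _, _ = self._flat_arrays()
        return phi.size

    @property
    def phi_max(self) -> np.ndarray:
        """Per-variant phi_max, flattened row-major (theta fastest)."""
        return self._flat_arrays()[0]

    @property
    def theta(self) -> np.ndarray:
        """Per-variant theta, flattened row-major (theta fastest)."""
        return self._flat_arrays()[1]

    @property
    def scenario(self) -> str:
        _, theta, _, n_theta = self._flat_arrays()
        return "constant-propensity" if np.all(theta == 0) else "communication"

    def _flat_arrays(self):
        if getattr(self, "_flat", None) is None:
            n_phi, n_theta = self.phi_axis.size, self.theta_axis.size
            phi = np.repeat(self.phi_axis, n_theta)
            theta = np.tile(self.theta_axis, n_phi)
            phi.setflags(write=False)
            theta.setflags(write=False)
            object.__setattr__(self, "_flat", (phi, theta, n_phi, n_theta))
        return self._flat

    def traits(self, index: int) -> tuple:
        """(phi_max, theta) of the flattened variant ``index``."""
        phi, theta, _, _ = self._flat_arrays()
        return float(phi[index]), float(theta[index])

    def labels(self) -> list:
        return [f"phi{p:g}_theta{t:g}" for p, t in zip(self.phi_max, self.theta)]
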