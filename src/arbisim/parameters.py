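"""Model parameters, dimensional and nondimensionalised.

The dimensional model tracks susceptible bacteria S, lysogens L_i, free
phages P_i (one class per phage variant i) and the arbitrium concentration
A.  Rescaling by the bacterial carrying capacity K and net growth rate r
(s = S/K, l = L/K, p = bP/K, A in units of cK, tau = r t) closes the system
over five dimensionless parameters: the effective burst size bB, the scaled
adsorption rate aK/r, the scaled phage decay rate delta/r, the scaled
spontaneous-induction rate alpha/r and the scaled arbitrium uptake rate
uK/r.  Serial-passaging settings (episode duration T, dilution factor D)
and the per-replication mutation probabilities ride along in
:class:`ScaledParameters` because every simulation needs them together.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any


def _require_positive(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not value > 0:
            raise ValueError(f"parameter {name!r} must be strictly positive, got {value!r}")


@dataclass(frozen=True)
class DimensionalParameters:
    """Dimensional model parameters.

    Attributes
    ----------
    r : bacterial net replication rate (per hour).
    K : bacterial carrying capacity (cells per mL).
    a : phage adsorption rate (per hour per (cells/mL)).
    b : probability that adsorption to a susceptible cell yields infection.
    B : burst size (phages released per lysis).
    alpha : spontaneous lysogen induction rate (per hour).
    delta : free-phage decay rate (per hour).
    u : arbitrium uptake rate (per (cells/mL) per hour).
    c : arbitrium released per infection (concentration units).
    """

    r: float = 1.0
    K: float = 1e9
    a: float = 1e-8
    b: float = 1e-2
    B: float = 200.0
    alpha: float = 1e-3
    delta: float = 1e-2
    u: float = 1e-10
    c: float = 1.0

    def __post_init__(self) -> None:
        _require_positive(
            r=self.r, K=self.K, a=self.a, b=self.b, B=self.B,
            alpha=self.alpha, delta=self.delta, u=self.u, c=self.c,
        )
        if self.b > 1:
            raise ValueError(f"infection probability b must lie in (0, 1], got {self.b!r}")

    def scaled(self, **overrides: Any) -> "ScaledParameters":
        """Nondimensionalise: s=S/K, l=L/K, p=bP/K, A in cK units, tau=rt."""
        params = ScaledParameters(
            B_eff=self.b * self.B,
            a_hat=self.a * self.K / self.r,
            delta_hat=self.delta / self.r,
            alpha_hat=self.alpha / self.r,
            u_hat=self.u * self.K / self.r,
        )
        return replace(params, **overrides) if overrides else params


@dataclass(frozen=True)
class ScaledParameters:
    """Dimensionless model parameters plus passaging and mutation settings.

    Defaults are the literature-motivated reference values; with r = 1/h
    scaled time equals hours, so ``T`` is stated in hours.
    ``growth_switch`` multiplies the logistic growth terms and exists so
    that conservation properties of the infection subsystem can be probed;
    it is 1 in every production run.
    """

    B_eff: float = 2.0
    a_hat: float = 10.0
    delta_hat: float = 0.01
    alpha_hat: float = 1e-3
    u_hat: float = 0.1
    D: float = 0.01
    T: float = 12.0
    mu_phi: float = 0.01
    mu_theta: float = 0.01
    growth_switch: float = 1.0

    def __post_init__(self) -> None:
        _require_positive(
            B_eff=self.B_eff, a_hat=self.a_hat, delta_hat=self.delta_hat,
            alpha_hat=self.alpha_hat, u_hat=self.u_hat, T=self.T,
        )
        if not 0 < self.D <= 1:
            raise ValueError(f"dilution factor D must lie in (0, 1], got {self.D!r}")
        for name in ("mu_phi", "mu_theta"):
            mu = getattr(self, name)
            if not 0 <= mu < 1:
                raise ValueError(f"mutation probability {name} must lie in [0, 1), got {mu!r}")
        if self.growth_switch not in (0, 0.0, 1, 1.0):
            raise ValueError("growth_switch must be 0 or 1")

    def replace(self, **overrides: Any) -> "ScaledParameters":
        return replace(self, **overrides)
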