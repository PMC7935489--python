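"""Scaled population dynamics of temperate phages with arbitrium signalling.

The model follows susceptible bacteria, per-variant lysogens and free
phages, and the extracellular arbitrium concentration in a well-mixed
volume.  In scaled units (densities in K, phages in K/b, arbitrium in cK,
time in 1/r) the dynamics within one passaging episode read

    ds/dt   = g s (1 - n/k) - a_hat s sum_i p_i
    dl_i/dt = g l_i (1 - n/k) + phi_i(A) a_hat s p_i - alpha_hat l_i
    dp_i/dt = [M b]_i - delta_hat p_i - a_hat n p_i
    dA/dt   = a_hat s sum_i p_i - u_hat n A

with n = s + sum_i l_i the total bacterial density, b_i the burst influx
B_eff (alpha_hat l_i + (1 - phi_i(A)) a_hat s p_i), M the mutation
operator redistributing burst mass to neighbouring trait variants, and
phi_i(A) the step response: phage variant i lysogenises with propensity
phi_max_i once A reaches its threshold theta_i, and is fully lytic below.
Adsorption to any bacterium removes free phages (superinfection immunity
makes adsorption to lysogens a dead end); lysis is instantaneous.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .grid import VariantGrid
from .parameters import ScaledParameters

DEFAULT_RTOL = 1e-8
DEFAULT_ATOL = 1e-12


class IntegrationError(RuntimeError):
    """Episode integration failed; ``time`` is where the solver gave up."""

    def __init__(self, message: str, time: float):
        super().__init__(f"{message} (t = {time:.6g})")
        self.time = time


@dataclass
class SystemState:
    """Scaled state: susceptibles s, lysogens l, free phages p, arbitrium A.

    ``k`` is the episode's carrying capacity (units K); it is a parameter
    of the episode rather than a dynamical variable but travels with the
    state because passaging changes it.
    """

    s: float
    l: np.ndarray
    p: np.ndarray
    A: float
    k: float = 1.0

    def __post_init__(self) -> None:
        self.l = np.atleast_1d(np.asarray(self.l, dtype=float))
        self.p = np.atleast_1d(np.asarray(self.p, dtype=float))
        if self.l.shape != self.p.shape:
            raise ValueError("l and p must have the same length")
        if self.s < 0 or self.A < 0 or self.k <= 0 or np.any(self.l < 0) or np.any(self.p < 0):
            raise ValueError("state components must be non-negative (k strictly positive)")

    @property
    def n_variants(self) -> int:
        return self.l.size

    @property
    def n_bacteria(self) -> float:
        return float(self.s + self.l.sum())

    def pack(self) -> np.ndarray:
        return np.concatenate(([self.s], self.l, self.p, [self.A]))

    @classmethod
    def unpack(cls, y: np.ndarray, k: float, *, validate: bool = True) -> "SystemState":
        nv = (y.size - 2) // 2
        state = cls.__new__(cls)
        state.s = float(y[0])
        state.l = np.array(y[1:1 + nv])
        state.p = np.array(y[1 + nv:1 + 2 * nv])
        state.A = float(y[1 + 2 * nv])
        state.k = k
        if validate:
            state.__post_init__()
        return state


@dataclass
class EpisodeTrajectory:
    """Time-ordered states of one passaging episode (accepted solver steps)."""

    times: np.ndarray
    ys: np.ndarray
    k: float

    @property
    def T(self) -> float:
        return float(self.times[-1])

    @property
    def n_variants(self) -> int:
        return (self.ys.shape[1] - 2) // 2

    @property
    def s(self) -> np.ndarray:
        return self.ys[:, 0]

    @property
    def l(self) -> np.ndarray:
        return self.ys[:, 1:1 + self.n_variants]

    @property
    def p(self) -> np.ndarray:
        return self.ys[:, 1 + self.n_variants:1 + 2 * self.n_variants]

    @property
    def A(self) -> np.ndarray:
        return self.ys[:, -1]

    def state(self, index: int) -> SystemState:
        return SystemState.unpack(self.ys[index], self.k)

    def final_state(self) -> SystemState:
        return self.state(-1)

    def to_frame(self, grid: VariantGrid | None = None):
        """Tidy table: time, s, A, k, then l and p per variant."""
        import pandas as pd

        labels = grid.labels() if grid is not None else [str(i) for i in range(self.n_variants)]
        data = {"time": self.times, "s": self.s, "A": self.A, "k": np.full(self.times.size, self.k)}
        for j, lab in enumerate(labels):
            data[f"l_{lab}"] = self.l[:, j]
        for j, lab in enumerate(labels):
            data[f"p_{lab}"] = self.p[:, j]
        return pd.DataFrame(data)


def lysogeny_propensity(phi_max, theta, A):
    """Step response of the lysis-lysogeny decision to the arbitrium signal.

    Returns phi_max where A >= theta and 0 below; theta = 0 gives the
    constant (signal-independent) propensity phi_max.  Vectorises over any
    argument.
    """
    phi_max = np.asarray(phi_max, dtype=float)
    theta = np.asarray(theta, dtype=float)
    A = np.asarray(A, dtype=float)
    if np.any(phi_max < 0) or np.any(phi_max > 1):
        raise ValueError("phi_max must lie in [0, 1]")
    if np.any(theta < 0) or np.any(A < 0):
        raise ValueError("theta and A must be non-negative")
    out = np.where(A >= theta, phi_max, 0.0)
    return float(out) if out.ndim == 0 else out


def _check_dims(state: SystemState, grid: VariantGrid) -> None:
    if state.n_variants != grid.n_variants:
        raise ValueError(
            f"state has {state.n_variants} variants but grid has {grid.n_variants}"
        )


def scaled_derivatives(state: SystemState, params: ScaledParameters, grid: VariantGrid) -> SystemState:
    """Right-hand side of the scaled system at ``state`` (k carried unchanged)."""
    _check_dims(state, grid)
    y = state.pack()
    out = np.empty_like(y)
    _kernels.rhs(
        y, state.k, params.B_eff, params.a_hat, params.delta_hat, params.alpha_hat,
        params.u_hat, params.growth_switch, grid.phi_max, grid.theta,
        grid.n_phi, grid.n_theta, params.mu_phi, params.mu_theta, out,
    )
    return SystemState.unpack(out, state.k, validate=False)


def mutation_operator(burst: np.ndarray, grid: VariantGrid, mu_phi: float, mu_theta: float) -> np.ndarray:
    """Redistribute burst mass to nearest trait neighbours; conserves the total.

    Per axis a fraction mu of each variant's mass moves to its grid
    neighbours, split equally when two exist; at a boundary the outward
    half-flux stays put.  The two axes act as sequential linear operators.
    """
    burst = np.asarray(burst, dtype=float)
    if burst.size != grid.n_variants:
        raise ValueError("burst length does not match grid")
    if np.any(burst < 0):
        raise ValueError("burst mass must be non-negative")
    out = np.empty_like(burst)
    _kernels.mutate_axes(burst, grid.n_phi, grid.n_theta, mu_phi, mu_theta, out)
    return out


def integrate_episode(
    state0: SystemState,
    params: ScaledParameters,
    grid: VariantGrid,
    *,
    T: float | None = None,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    store: bool = True,
    negative_tol: float | None = None,
) -> EpisodeTrajectory:
    """Integrate one passaging episode over [0, T] (T defaults to params.T).

    Adaptive embedded Runge-Kutta (Dormand-Prince 5(4)); accepted steps are
    stored unless ``store`` is false, in which case only the endpoint state
    is kept (the fast path for long passaging runs).  Negative solver
    excursions up to ``negative_tol`` (default: 10 (atol + rtol max|y|),
    i.e. a small multiple of the local error scale) are clipped to zero;
    larger ones raise IntegrationError.
    """
    _check_dims(state0, grid)
    if T is None:
        T = params.T
    if not T > 0:
        raise ValueError("episode duration T must be positive")
    ts, ys, status, t_fail = _kernels.integrate(
        state0.pack(), float(T), state0.k, params.B_eff, params.a_hat,
        params.delta_hat, params.alpha_hat, params.u_hat, params.growth_switch,
        grid.phi_max, grid.theta, grid.n_phi, grid.n_theta,
        params.mu_phi, params.mu_theta, rtol, atol,
        -1.0 if negative_tol is None else float(negative_tol), store,
    )
    if status == _kernels.STATUS_STEP_COLLAPSE:
        raise IntegrationError("step size collapsed", t_fail)
    if status == _kernels.STATUS_NEGATIVE:
        raise IntegrationError("state went negative beyond solver tolerance", t_fail)
    return EpisodeTrajectory(times=ts, ys=ys, k=state0.k)
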