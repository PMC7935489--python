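"""Evolutionarily stable strategies and ecological equilibria.

Two closed-form ESS approximations hold when the interval between
passages is long enough that every epidemic runs to susceptible-cell
collapse:

* constant lysogeny propensity (bet-hedging):
  ``phi* = 1 - (bB)^-1 log(B K / P0)``, with P0 the phage density at the
  start of an episode (natural log; clamped to [0, 1] since the raw
  expression goes negative for weakly infective phages);
* communication threshold (phages with phi_max = 1):
  ``theta* = cK / (2 - (bB)^-1)``, i.e. switch to lysogeny once a fraction
  1/(2 - 1/bB) of the susceptible pool has been infected, approaching
  one half for highly infective phages.

The numerical ESS machinery implements the fixed-point construction
directly: the epidemic collapse time T_E depends on the resident strategy,
the optimal rare invader depends on T_E (it maximises lysogens produced
per capita on the frozen resident background), and the ESS is the strategy
that is the optimal response to itself.

Separately, :func:`find_equilibria` locates and classifies the fixed
points of the un-passaged single-variant system: the phage-free state,
coexistence of susceptibles/lysogens/phages (type i) and the lysogen-only
state in which every susceptible cell has been infected (type ii).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.interpolate import CubicHermiteSpline
from scipy.optimize import minimize_scalar, root

from . import _kernels
from .dynamics import EpisodeTrajectory, SystemState, integrate_episode, scaled_derivatives
from .grid import VariantGrid
from .parameters import ScaledParameters

__all__ = [
    "EssResult",
    "Equilibrium",
    "EquilibriumReport",
    "phi_star_closed_form",
    "phi_star_scaled",
    "theta_star_closed_form",
    "steady_passaging_p0",
    "resident_background",
    "epidemic_duration",
    "invader_lysogen_yield",
    "optimal_invader_trait",
    "ess_fixed_point",
    "find_equilibria",
]


# ---------------------------------------------------------------------------
# closed forms
# ---------------------------------------------------------------------------

def phi_star_closed_form(b: float, B: float, K: float, P0: float, *, clamp: bool = True) -> float:
    """Closed-form ESS lysogeny propensity [1 - (bB)^-1] / log(BK / P0).

    ``P0`` is the phage density at the start of a passaging episode and
    the logarithm is natural.  At the reference conditions (bB = 2,
    P0 = 1e-5 K B) this evaluates to 0.043, matching the propensity
    selected in simulation.  With ``clamp`` (default) the value is clamped
    to [0, 1]: the raw expression is negative for bB < 1 (lysogeny never
    pays) and diverges as P0 approaches BK (no epidemic at all).
    """
    for name, v in (("b", b), ("B", B), ("K", K), ("P0", P0)):
        if not v > 0:
            raise ValueError(f"{name} must be strictly positive")
    if P0 >= B * K:
        return 1.0 if clamp else math.inf
    raw = (1.0 - 1.0 / (b * B)) / math.log(B * K / P0)
    return min(max(raw, 0.0), 1.0) if clamp else raw


def phi_star_scaled(B_eff: float, p0: float, *, clamp: bool = True) -> float:
    """Scaled form of the ESS propensity: [1 - 1/B_eff] / log(B_eff / p0).

    ``p0`` is the scaled phage density b P0 / K at episode start, so
    B K / P0 = B_eff / p0.
    """
    if not (B_eff > 0 and p0 > 0):
        raise ValueError("B_eff and p0 must be strictly positive")
    if p0 >= B_eff:
        return 1.0 if clamp else math.inf
    raw = (1.0 - 1.0 / B_eff) / math.log(B_eff / p0)
    return min(max(raw, 0.0), 1.0) if clamp else raw


def theta_star_closed_form(B_eff: float) -> float:
    """Closed-form ESS response threshold (units cK): 1 / (2 - 1/B_eff).

    Strictly decreasing in the effective burst size, from 1 at B_eff = 1
    towards the limit 1/2 for highly infective phages.  Only defined for
    B_eff > 1/2 (the denominator changes sign below).
    """
    if not B_eff > 0.5:
        raise ValueError("theta* requires effective burst size B_eff > 0.5")
    return 1.0 / (2.0 - 1.0 / B_eff)


# ---------------------------------------------------------------------------
# resident backgrounds
# ---------------------------------------------------------------------------

def _resident_grid(trait: float, axis: str) -> VariantGrid:
    if axis == "phi":
        return VariantGrid.single(trait, 0.0)
    if axis == "theta":
        return VariantGrid.single(1.0, trait)
    raise ValueError(f"axis must be 'phi' or 'theta', got {axis!r}")


def steady_passaging_p0(
    trait: float,
    params: ScaledParameters,
    axis: str = "phi",
    *,
    p0_init: Optional[float] = None,
    tol: float = 1e-6,
    max_cycles: int = 200,
) -> float:
    """Self-consistent episode-start phage density under steady passaging.

    Iterates monomorphic episodes p0 -> D * p_end(p0) until the start
    density stabilises (relative change < tol).  Mutation is irrelevant
    for a single variant.
    """
    grid = _resident_grid(trait, axis)
    p0 = p0_init if p0_init is not None else 1e-5 * params.B_eff
    for _ in range(max_cycles):
        state = SystemState(s=1.0, l=[0.0], p=[p0], A=0.0)
        traj = integrate_episode(state, params, grid, store=False)
        p0_new = params.D * float(traj.final_state().p.sum())
        if p0_new <= 0:
            raise RuntimeError("resident phage population is not viable under passaging")
        if abs(p0_new - p0) <= tol * p0:
            return p0_new
        p0 = p0_new
    return p0


def resident_background(
    trait: float,
    params: ScaledParameters,
    axis: str = "phi",
    *,
    p0: Optional[float] = None,
    t_max: Optional[float] = None,
) -> EpisodeTrajectory:
    """Monomorphic resident episode trajectory (for invasion analysis).

    Starts from s = 1, p = p0 (steady-passaging density unless given) and
    integrates for ``t_max`` (default 10 T) so that the collapse time is
    always contained in the stored trajectory.
    """
    grid = _resident_grid(trait, axis)
    if p0 is None:
        p0 = steady_passaging_p0(trait, params, axis)
    if t_max is None:
        t_max = 10.0 * params.T
    state = SystemState(s=1.0, l=[0.0], p=[p0], A=0.0)
    return integrate_episode(state, params, grid, T=t_max, store=True)


def _hermite(traj: EpisodeTrajectory, params: ScaledParameters, grid: VariantGrid):
    """C1 interpolants of s(t), n(t), A(t) from the stored solver steps."""
    derivs = np.empty_like(traj.ys)
    for i in range(traj.times.size):
        _kernels.rhs(
            traj.ys[i], traj.k, params.B_eff, params.a_hat, params.delta_hat,
            params.alpha_hat, params.u_hat, params.growth_switch,
            grid.phi_max, grid.theta, grid.n_phi, grid.n_theta,
            params.mu_phi, params.mu_theta, derivs[i],
        )
    nv = traj.n_variants
    s = CubicHermiteSpline(traj.times, traj.ys[:, 0], derivs[:, 0])
    n = CubicHermiteSpline(
        traj.times,
        traj.ys[:, 0] + traj.ys[:, 1:1 + nv].sum(axis=1),
        derivs[:, 0] + derivs[:, 1:1 + nv].sum(axis=1),
    )
    A = CubicHermiteSpline(traj.times, traj.ys[:, -1], derivs[:, -1])
    return s, n, A


def epidemic_duration(
    resident_traits,
    params: ScaledParameters,
    p0: Optional[float] = None,
    collapse_eps: float = 1e-3,
    *,
    trajectory: Optional[EpisodeTrajectory] = None,
    t_max: Optional[float] = None,
) -> Optional[float]:
    """Time at which the resident epidemic depletes the susceptible pool.

    Defined as the first time s(t) falls below ``collapse_eps`` times the
    episode carrying capacity; located by root-finding on the trajectory
    interpolant.  Returns None when no collapse occurs before ``t_max``
    (default 10 T).

    ``resident_traits`` is (phi_max, theta) or a bare constant propensity.
    """
    phi_max, theta = _as_traits(resident_traits)
    grid = VariantGrid.single(phi_max, theta)
    if trajectory is None:
        if t_max is None:
            t_max = 10.0 * params.T
        if p0 is None:
            axis = "theta" if theta > 0 else "phi"
            trait = theta if theta > 0 else phi_max
            p0 = steady_passaging_p0(trait, params, axis)
        state = SystemState(s=1.0, l=[0.0], p=[p0], A=0.0)
        trajectory = integrate_episode(state, params, grid, T=t_max, store=True)
    s_spline, _, _ = _hermite(trajectory, params, grid)
    target = collapse_eps * trajectory.k
    svals = trajectory.s
    below = np.flatnonzero(svals < target)
    if below.size == 0:
        return None
    i = below[0]
    if i == 0:
        return 0.0
    from scipy.optimize import brentq

    return float(brentq(lambda t: s_spline(t) - target, trajectory.times[i - 1], trajectory.times[i]))


def _phage_bloom_end(traj: EpisodeTrajectory, eps: float) -> Optional[float]:
    """First time after the free-phage peak that total p falls below eps * peak."""
    ptot = traj.p.sum(axis=1)
    ipk = int(np.argmax(ptot))
    if ptot[ipk] <= 0:
        return None
    below = np.flatnonzero(ptot[ipk:] < eps * ptot[ipk])
    if below.size == 0:
        return None
    return float(traj.times[ipk + below[0]])


def _as_traits(resident_traits) -> tuple:
    if np.isscalar(resident_traits):
        return float(resident_traits), 0.0
    phi_max, theta = resident_traits
    return float(phi_max), float(theta)


def invader_lysogen_yield(
    invader_traits,
    resident_trajectory: EpisodeTrajectory,
    T_E: float,
    params: ScaledParameters,
    *,
    resident_grid: Optional[VariantGrid] = None,
    rtol: float = 1e-8,
    atol: float = 1e-14,
) -> float:
    """Lysogens produced per invading phage on the frozen resident background.

    Integrates the linearised (rare-invader) lysogen/phage pair on the
    resident's s(t), n(t), A(t) from 0 to T_E with p_inv(0) = 1,
    l_inv(0) = 0 and returns l_inv(T_E).  Exact in the rare-invader limit;
    the nonlinear two-variant simulation reproduces it (see tests).
    """
    if T_E > resident_trajectory.T + 1e-12:
        raise ValueError("resident trajectory does not span [0, T_E]")
    phi_max_i, theta_i = _as_traits(invader_traits)
    if resident_grid is None:
        resident_grid = VariantGrid.single(1.0, 0.0)  # traits only affect phi(A) below
        # background interpolants do not depend on the invader's traits
    s_sp, n_sp, A_sp = _hermite(resident_trajectory, params, resident_grid)
    g = params.growth_switch
    k = resident_trajectory.k

    def make_rhs(phi: float):
        def rhs(t, y):
            l_inv, p_inv = y
            s = max(float(s_sp(t)), 0.0)
            n = max(float(n_sp(t)), 0.0)
            inf = params.a_hat * s * p_inv
            dl = g * l_inv * (1.0 - n / k) + phi * inf - params.alpha_hat * l_inv
            dp = params.B_eff * (params.alpha_hat * l_inv + (1.0 - phi) * inf) \
                - params.delta_hat * p_inv - params.a_hat * n * p_inv
            return (dl, dp)

        return rhs

    if T_E <= 0:
        return 0.0
    # the invader's response switches where A(t) crosses its threshold;
    # integrate the linear system piecewise between crossings so every
    # segment has a smooth right-hand side
    if theta_i > 0:
        crossings = sorted(
            float(t) for t in A_sp.solve(theta_i, extrapolate=False)
            if 0.0 < t < T_E
        )
    else:
        crossings = []
    edges = [0.0] + crossings + [T_E]
    y = [0.0, 1.0]
    for a, b in zip(edges[:-1], edges[1:]):
        if b - a <= 1e-15:
            continue
        mid = 0.5 * (a + b)
        phi = phi_max_i if float(A_sp(mid)) >= theta_i else 0.0
        sol = solve_ivp(make_rhs(phi), (a, b), y, method="RK45", rtol=rtol, atol=atol)
        if not sol.success:
            raise RuntimeError(f"invader integration failed: {sol.message}")
        y = [float(sol.y[0, -1]), float(sol.y[1, -1])]
    return float(max(y[0], 0.0))


def optimal_invader_trait(
    T_E: float,
    params: ScaledParameters,
    axis: str,
    resident_trajectory: EpisodeTrajectory,
    *,
    resident_grid: Optional[VariantGrid] = None,
    coarse: int = 21,
) -> float:
    """Invader trait maximising per-capita lysogen yield up to time T_E.

    Grid search over [0, 1] (propensity, or threshold in cK units with
    phi_max = 1) followed by bounded local refinement.  A flat objective
    reports the lowest optimal trait.
    """
    if axis not in ("phi", "theta"):
        raise ValueError("axis must be 'phi' or 'theta'")

    def yield_of(x: float) -> float:
        traits = (x, 0.0) if axis == "phi" else (1.0, x)
        return invader_lysogen_yield(traits, resident_trajectory, T_E, params,
                                     resident_grid=resident_grid)

    xs = np.linspace(0.0, 1.0, coarse)
    ys = np.array([yield_of(x) for x in xs])
    best = int(np.argmax(ys))
    if ys[best] <= 0 or np.allclose(ys, ys[0], rtol=1e-12, atol=0):
        return float(xs[np.flatnonzero(ys == ys.max())[0]])
    lo = xs[max(best - 1, 0)]
    hi = xs[min(best + 1, coarse - 1)]
    res = minimize_scalar(lambda x: -yield_of(x), bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-4})
    return float(res.x) if -res.fun >= ys[best] else float(xs[best])


@dataclass
class EssResult:
    """Outcome of an ESS computation."""

    axis: str
    value: float
    method: str                 # "closed_form" or "fixed_point"
    T_E: Optional[float] = None
    residual: Optional[float] = None
    clamped: bool = False
    iterations: int = 0


def ess_fixed_point(
    params: ScaledParameters,
    axis: str,
    *,
    tol: float = 1e-3,
    max_iter: int = 60,
    damping: float = 0.5,
    collapse_eps: float = 1e-3,
    x0: Optional[float] = None,
) -> EssResult:
    """ESS by damped fixed-point iteration of trait -> optimal response.

    Each step simulates the monomorphic resident to susceptible collapse
    (its steady-passaging start density), finds the optimal rare invader
    on that background, and relaxes the resident towards it.  Falls back
    to bisection on (optimal response - trait) if the damped iteration
    cycles.
    """
    if axis not in ("phi", "theta"):
        raise ValueError("axis must be 'phi' or 'theta'")

    def respond(x: float):
        traj = resident_background(x, params, axis)
        traits = (x, 0.0) if axis == "phi" else (1.0, x)
        grid = _resident_grid(x, axis)
        T_E = epidemic_duration(traits, params, trajectory=traj, collapse_eps=collapse_eps)
        if T_E is None:
            # communication residents can halt the epidemic by switching to
            # lysogeny before the susceptibles collapse; the epidemic is then
            # over once the free-phage bloom has been adsorbed away
            T_E = _phage_bloom_end(traj, collapse_eps)
        if T_E is None:
            raise RuntimeError(
                f"resident {axis}={x:.4g} produces no epidemic "
                "(neither susceptibles nor the phage bloom collapse)"
            )
        return optimal_invader_trait(T_E, params, axis, traj, resident_grid=grid), T_E

    # start low on the phi axis: high-propensity residents are not viable
    # under 100-fold dilution (they replicate too slowly to recover)
    x = x0 if x0 is not None else (0.1 if axis == "phi" else 0.5)
    T_E = None
    history = []
    last_good = x
    for it in range(1, max_iter + 1):
        try:
            fx, T_E = respond(x)
        except RuntimeError:
            # iterate left the viable region; back off towards the last
            # viable trait value
            x = 0.5 * (x + last_good)
            continue
        last_good = x
        resid = abs(fx - x)
        if resid < tol:
            return EssResult(axis=axis, value=x, method="fixed_point",
                             T_E=T_E, residual=resid, iterations=it)
        history.append((x, fx))
        x = (1.0 - damping) * x + damping * fx
        if it >= 8 and len(history) >= 4:
            # cycling: fall back to bisection on g(x) = f(x) - x
            gs = [(xi, fi - xi) for xi, fi in history]
            neg = [xi for xi, gi in gs if gi < 0]
            pos = [xi for xi, gi in gs if gi > 0]
            if neg and pos:
                lo, hi = min(neg + pos), max(neg + pos)
                for _ in range(40):
                    mid = 0.5 * (lo + hi)
                    fm, T_E = respond(mid)
                    if abs(fm - mid) < tol:
                        return EssResult(axis=axis, value=mid, method="fixed_point",
                                         T_E=T_E, residual=abs(fm - mid), iterations=it)
                    if fm > mid:
                        lo = mid
                    else:
                        hi = mid
                    if hi - lo < tol:
                        return EssResult(axis=axis, value=0.5 * (lo + hi), method="fixed_point",
                                         T_E=T_E, residual=hi - lo, iterations=it)
                break
    raise RuntimeError(f"ESS fixed-point iteration did not converge on axis {axis!r}")


# ---------------------------------------------------------------------------
# equilibria of the un-passaged system
# ---------------------------------------------------------------------------

@dataclass
class Equilibrium:
    state: np.ndarray            # [s, l, p, A]
    classification: str          # phage_free | coexistence_type_i | lysogen_only_type_ii
    leading_eigenvalue: float
    stable: bool
    residual: float


@dataclass
class EquilibriumReport:
    equilibria: list

    def of_type(self, classification: str) -> list:
        return [e for e in self.equilibria if e.classification == classification]


def _classify(y: np.ndarray, tol: float = 1e-8) -> str:
    s, l, p, _ = y
    if p <= tol and l <= tol:
        return "phage_free"
    if s <= tol:
        return "lysogen_only_type_ii"
    return "coexistence_type_i"


def find_equilibria(
    params: ScaledParameters,
    constant_phi: float,
    *,
    k: float = 1.0,
    n_starts: int = 60,
    seed: int = 0,
    residual_tol: float = 1e-10,
) -> EquilibriumReport:
    """Locate and classify equilibria of the single-variant system.

    Multi-start Newton (scipy ``root``) from analytic seeds (phage-free
    and lysogen-only states) plus random positive states; candidates with
    residual norm above ``residual_tol`` or negative components are
    rejected.  Stability is judged from the numerically differentiated
    Jacobian's leading eigenvalue.
    """
    if not 0 <= constant_phi <= 1:
        raise ValueError("constant_phi must lie in [0, 1]")
    grid = VariantGrid.single(constant_phi, 0.0)
    params = params.replace(mu_phi=0.0, mu_theta=0.0)

    def f(y: np.ndarray) -> np.ndarray:
        out = np.empty(4)
        _kernels.rhs(y, k, params.B_eff, params.a_hat, params.delta_hat,
                     params.alpha_hat, params.u_hat, params.growth_switch,
                     grid.phi_max, grid.theta, 1, 1, 0.0, 0.0, out)
        return out

    def jac(y: np.ndarray, eps: float = 1e-7) -> np.ndarray:
        J = np.empty((4, 4))
        f0 = f(y)
        for j in range(4):
            step = eps * max(abs(y[j]), 1.0)
            yp = y.copy()
            yp[j] += step
            J[:, j] = (f(yp) - f0) / step
        return J

    l_only = k * (1.0 - params.alpha_hat)
    p_only = params.B_eff * params.alpha_hat * l_only / (params.delta_hat + params.a_hat * l_only)
    seeds = [
        np.array([k, 0.0, 0.0, 0.0]),
        np.array([0.0, l_only, p_only, 0.0]),
    ]
    rng = np.random.default_rng(seed)
    for _ in range(n_starts):
        seeds.append(np.array([
            rng.uniform(0, k), rng.uniform(0, k),
            10 ** rng.uniform(-4, 1), 10 ** rng.uniform(-4, 1),
        ]))

    found: list = []
    for y0 in seeds:
        sol = root(f, y0, method="hybr", tol=1e-13)
        y = sol.x
        resid = float(np.linalg.norm(f(y)))
        if resid > residual_tol:
            continue
        if np.any(y < -1e-9):
            continue
        y = np.clip(y, 0.0, None)
        if y[0] + y[1] <= 1e-8:
            continue  # extinct bacterial population: a degenerate invariant manifold
        if any(np.allclose(y, e.state, rtol=1e-6, atol=1e-9) for e in found):
            continue
        eigs = np.linalg.eigvals(jac(y))
        lead = float(np.max(eigs.real))
        found.append(Equilibrium(
            state=y,
            classification=_classify(y),
            leading_eigenvalue=lead,
            stable=lead < 0,
            residual=resid,
        ))
    found.sort(key=lambda e: (e.classification, e.state[0]))
    return EquilibriumReport(equilibria=found)
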