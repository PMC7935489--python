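"""Compiled numerical kernels: scaled RHS, mutation flux, adaptive RK stepper.

A single passaging run integrates the scaled system through hundreds to
thousands of episodes at up to ~900 state dimensions, so the inner loop is
fully jitted: the right-hand side, the nearest-neighbour mutation operator
and a Dormand-Prince 5(4) embedded Runge-Kutta pair with standard PI-free
step control (the same tableau scipy's RK45 uses; agreement with
scipy.solve_ivp is asserted in the test suite).

State packing convention (dimension 2*nv + 2 for nv variants):

    y = [s, l_1..l_nv, p_1..p_nv, A]

Status codes returned by the integrator: 0 success, 1 step-size collapse,
2 negative component beyond the clipping tolerance.
"""

import numpy as np
from numba import njit

STATUS_OK = 0
STATUS_STEP_COLLAPSE = 1
STATUS_NEGATIVE = 2

# Dormand-Prince 5(4) tableau
_C = np.array([0.0, 1 / 5, 3 / 10, 4 / 5, 8 / 9, 1.0, 1.0])
_A21 = 1 / 5
_A31, _A32 = 3 / 40, 9 / 40
_A41, _A42, _A43 = 44 / 45, -56 / 15, 32 / 9
_A51, _A52, _A53, _A54 = 19372 / 6561, -25360 / 2187, 64448 / 6561, -212 / 729
_A61, _A62, _A63, _A64, _A65 = 9017 / 3168, -355 / 33, 46732 / 5247, 49 / 176, -5103 / 18656
_B1, _B3, _B4, _B5, _B6 = 35 / 384, 500 / 1113, 125 / 192, -2187 / 6784, 11 / 84
# b - bhat (5th-order weights minus embedded 4th-order weights)
_E1, _E3, _E4, _E5, _E6, _E7 = (
    71 / 57600, -71 / 16695, 71 / 1920, -17253 / 339200, 22 / 525, -1 / 40,
)


@njit(cache=True)
def mutate_axes(x, n_phi, n_theta, mu_phi, mu_theta, out):
    """Apply nearest-neighbour mutation along both trait axes of the lattice.

    ``x`` is the flattened (n_phi, n_theta) burst vector, theta fastest.
    Per axis, a fraction mu of each variant's mass moves to its neighbours
    (split equally when two exist); at the lattice boundary the outward
    half-flux stays with the source.  Axes are applied sequentially; each
    pass conserves total mass exactly.
    """
    nv = n_phi * n_theta
    tmp = np.empty(nv)
    # phi axis: stride n_theta
    if mu_phi > 0.0 and n_phi > 1:
        half = 0.5 * mu_phi
        for j in range(n_theta):
            for i in range(n_phi):
                idx = i * n_theta + j
                stay = 1.0 - mu_phi
                if i == 0 or i == n_phi - 1:
                    stay = 1.0 - half
                acc = stay * x[idx]
                if i > 0:
                    acc += half * x[(i - 1) * n_theta + j]
                if i < n_phi - 1:
                    acc += half * x[(i + 1) * n_theta + j]
                tmp[idx] = acc
    else:
        for idx in range(nv):
            tmp[idx] = x[idx]
    # theta axis: stride 1
    if mu_theta > 0.0 and n_theta > 1:
        half = 0.5 * mu_theta
        for i in range(n_phi):
            base = i * n_theta
            for j in range(n_theta):
                idx = base + j
                stay = 1.0 - mu_theta
                if j == 0 or j == n_theta - 1:
                    stay = 1.0 - half
                acc = stay * tmp[idx]
                if j > 0:
                    acc += half * tmp[idx - 1]
                if j < n_theta - 1:
                    acc += half * tmp[idx + 1]
                out[idx] = acc
    else:
        for idx in range(nv):
            out[idx] = tmp[idx]
    return out


@njit(cache=True)
def rhs(y, k, B_eff, a_hat, delta_hat, alpha_hat, u_hat, g,
        phi_max, theta, n_phi, n_theta, mu_phi, mu_theta, out):
    """Scaled derivatives of [s, l, p, A]; ``k`` is the episode carrying capacity."""
    nv = phi_max.size
    s = y[0]
    A = y[1 + 2 * nv]
    n_tot = s
    for i in range(nv):
        n_tot += y[1 + i]
    logistic = g * (1.0 - n_tot / k)
    psum = 0.0
    for i in range(nv):
        psum += y[1 + nv + i]
    infect = a_hat * s
    burst = np.empty(nv)
    for i in range(nv):
        li = y[1 + i]
        pi = y[1 + nv + i]
        phi = phi_max[i] if A >= theta[i] else 0.0
        out[1 + i] = logistic * li + phi * infect * pi - alpha_hat * li
        burst[i] = B_eff * (alpha_hat * li + (1.0 - phi) * infect * pi)
    mutated = np.empty(nv)
    mutate_axes(burst, n_phi, n_theta, mu_phi, mu_theta, mutated)
    for i in range(nv):
        pi = y[1 + nv + i]
        out[1 + nv + i] = mutated[i] - delta_hat * pi - a_hat * n_tot * pi
    out[0] = logistic * s - infect * psum
    out[1 + 2 * nv] = infect * psum - u_hat * n_tot * A
    return out


@njit(cache=True)
def _error_norm(err, y0, y1, rtol, atol):
    dim = err.size
    acc = 0.0
    for i in range(dim):
        scale = atol + rtol * max(abs(y0[i]), abs(y1[i]))
        e = err[i] / scale
        acc += e * e
    return np.sqrt(acc / dim)


@njit(cache=True)
def integrate(y0, t_end, k, B_eff, a_hat, delta_hat, alpha_hat, u_hat, g,
              phi_max, theta, n_phi, n_theta, mu_phi, mu_theta,
              rtol, atol, neg_tol, store):
    """Integrate the scaled system from 0 to t_end.

    Returns (times, states, status, t_fail).  With ``store`` false only the
    initial and final states are kept.  After each accepted step, negative
    components smaller in magnitude than the clipping threshold are set to
    zero; larger negatives abort with STATUS_NEGATIVE.  The threshold is
    ``neg_tol`` when positive, otherwise the scale-aware default
    10 (atol + rtol max|y|).
    """
    dim = y0.size
    y = y0.copy()
    t = 0.0

    k1 = np.empty(dim)
    k2 = np.empty(dim)
    k3 = np.empty(dim)
    k4 = np.empty(dim)
    k5 = np.empty(dim)
    k6 = np.empty(dim)
    k7 = np.empty(dim)
    ytmp = np.empty(dim)
    ynew = np.empty(dim)
    err = np.empty(dim)

    rhs(y, k, B_eff, a_hat, delta_hat, alpha_hat, u_hat, g,
        phi_max, theta, n_phi, n_theta, mu_phi, mu_theta, k1)

    # initial step heuristic (scipy-like)
    d0 = _error_norm(y, y, y, rtol, atol)  # ~ |y|/scale
    d1 = _error_norm(k1, y, y, rtol, atol)
    if d0 < 1e-5 or d1 < 1e-5:
        h = 1e-6
    else:
        h = 0.01 * d0 / d1
    h = min(h, t_end)

    cap = 1024 if store else 2
    ts = np.empty(cap)
    ys = np.empty((cap, dim))
    ts[0] = 0.0
    ys[0, :] = y
    nstore = 1

    status = STATUS_OK
    t_fail = 0.0
    max_steps = 50_000_000
    steps = 0

    while t < t_end:
        if steps >= max_steps:
            status = STATUS_STEP_COLLAPSE
            t_fail = t
            break
        steps += 1
        # smallest meaningful step at the current time; at this size the
        # step is force-accepted (the RHS is discontinuous where the
        # arbitrium concentration crosses a response threshold, and error
        # control cannot shrink the local error there below atol for
        # components sitting at exactly zero)
        h_min = 3e-14 * max(t, 1.0)
        if h < h_min:
            h = h_min
        if t + h > t_end:
            h = t_end - t

        for i in range(dim):
            ytmp[i] = y[i] + h * _A21 * k1[i]
        rhs(ytmp, k, B_eff, a_hat, delta_hat, alpha_hat, u_hat, g,
            phi_max, theta, n_phi, n_theta, mu_phi, mu_theta, k2)
        for i in range(dim):
            ytmp[i] = y[i] + h * (_A31 * k1[i] + _A32 * k2[i])
        rhs(ytmp, k, B_eff, a_hat, delta_hat, alpha_hat, u_hat, g,
            phi_max, theta, n_phi, n_theta, mu_phi, mu_theta, k3)
        for i in range(dim):
            ytmp[i] = y[i] + h * (_A41 * k1[i] + _A42 * k2[i] + _A43 * k3[i])
        rhs(ytmp, k, B_eff, a_hat, delta_hat, alpha_hat, u_hat, g,
            phi_max, theta, n_phi, n_theta, mu_phi, mu_theta, k4)
        for i in range(dim):
            ytmp[i] = y[i] + h * (_A51 * k1[i] + _A52 * k2[i] + _A53 * k3[i] + _A54 * k4[i])
        rhs(ytmp, k, B_eff, a_hat, delta_hat, alpha_hat, u_hat, g,
            phi_max, theta, n_phi, n_theta, mu_phi, mu_theta, k5)
        for i in range(dim):
            ytmp[i] = y[i] + h * (_A61 * k1[i] + _A62 * k2[i] + _A63 * k3[i]
                                  + _A64 * k4[i] + _A65 * k5[i])
        rhs(ytmp, k, B_eff, a_hat, delta_hat, alpha_hat, u_hat, g,
            phi_max, theta, n_phi, n_theta, mu_phi, mu_theta, k6)
        for i in range(dim):
            ynew[i] = y[i] + h * (_B1 * k1[i] + _B3 * k3[i] + _B4 * k4[i]
                                  + _B5 * k5[i] + _B6 * k6[i])
        rhs(ynew, k, B_eff, a_hat, delta_hat, alpha_hat, u_hat, g,
            phi_max, theta, n_phi, n_theta, mu_phi, mu_theta, k7)
        for i in range(dim):
            err[i] = h * (_E1 * k1[i] + _E3 * k3[i] + _E4 * k4[i]
                          + _E5 * k5[i] + _E6 * k6[i] + _E7 * k7[i])
        enorm = _error_norm(err, y, ynew, rtol, atol)

        if enorm <= 1.0 or h <= h_min:
            if not np.isfinite(enorm):
                status = STATUS_STEP_COLLAPSE
                t_fail = t
                break
            t += h
            clipped = False
            if neg_tol > 0.0:
                thresh = neg_tol
            else:
                ymax = 0.0
                for i in range(dim):
                    if abs(ynew[i]) > ymax:
                        ymax = abs(ynew[i])
                thresh = 10.0 * (atol + rtol * ymax)
            for i in range(dim):
                if ynew[i] < 0.0:
                    if -ynew[i] > thresh:
                        status = STATUS_NEGATIVE
                        t_fail = t
                        break
                    ynew[i] = 0.0
                    clipped = True
            if status != STATUS_OK:
                break
            for i in range(dim):
                y[i] = ynew[i]
            if clipped:
                rhs(y, k, B_eff, a_hat, delta_hat, alpha_hat, u_hat, g,
                    phi_max, theta, n_phi, n_theta, mu_phi, mu_theta, k1)
            else:
                for i in range(dim):
                    k1[i] = k7[i]  # FSAL
            if store:
                if nstore == cap:
                    cap *= 2
                    ts2 = np.empty(cap)
                    ys2 = np.empty((cap, dim))
                    ts2[:nstore] = ts[:nstore]
                    ys2[:nstore, :] = ys[:nstore, :]
                    ts = ts2
                    ys = ys2
                ts[nstore] = t
                ys[nstore, :] = y
                nstore += 1
            if enorm == 0.0:
                factor = 10.0
            else:
                factor = min(10.0, max(0.2, 0.9 * enorm ** -0.2))
            h *= factor
        else:
            h *= max(0.2, 0.9 * enorm ** -0.2)

    if not store:
        ts[1] = t
        ys[1, :] = y
        nstore = 2
    elif status == STATUS_OK and ts[nstore - 1] < t_end:
        # t_end landed exactly on the last accepted step otherwise
        ts[nstore - 1] = t_end

    return ts[:nstore].copy(), ys[:nstore, :].copy(), status, t_fail
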