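"""Compiled inner loop of the stochastic Boussinesq integrator.

All fields are dimensionless.  The first-order system integrated is

    drho'/dt' = -du'/dx'
    du'/dt'   = -dg'/dx' + h'
    g' = k1' rho' - k2' rho'_xx + (alpha'/2) rho'^2 - nu' u'_x

where the damping term nu' * drho'/dt' inside the flux has been
rewritten as -nu' u'_x via the continuity equation, keeping the scheme
explicit and flux-local.  Time stepping is MacCormack
predictor/corrector with one-sided differences whose direction
alternates every step; the stochastic forcing h' is held fixed within
a step (Euler-Maruyama weighting).  Forcing values are generated by
the caller (NumPy Generator) and fed in blocks, so the noise stream is
a plain, reproducible sequence of standard normals.

Boundary modes: 0 = periodic, 1 = sponge taper, 2 = characteristic
outflow on Riemann-like variables u' +/- sqrt(k1') rho'.
"""

import numpy as np
from numba import njit

__all__ = ["run_chunk", "BC_PERIODIC", "BC_SPONGE", "BC_CHARACTERISTIC"]

BC_PERIODIC = 0
BC_SPONGE = 1
BC_CHARACTERISTIC = 2


@njit(cache=True)
def _compute_g(rho, u, dx, k1, k2, alpha, nu, periodic, g):
    n = rho.shape[0]
    inv_dx2 = 1.0 / (dx * dx)
    inv_2dx = 0.5 / dx
    for i in range(n):
        if periodic:
            ip = i + 1 if i + 1 < n else 0
            im = i - 1 if i - 1 >= 0 else n - 1
            lap = (rho[ip] - 2.0 * rho[i] + rho[im]) * inv_dx2
            ux = (u[ip] - u[im]) * inv_2dx
        else:
            if i == 0:
                lap = (rho[2] - 2.0 * rho[1] + rho[0]) * inv_dx2
                ux = (u[1] - u[0]) / dx
            elif i == n - 1:
                lap = (rho[n - 1] - 2.0 * rho[n - 2] + rho[n - 3]) * inv_dx2
                ux = (u[n - 1] - u[n - 2]) / dx
            else:
                lap = (rho[i + 1] - 2.0 * rho[i] + rho[i - 1]) * inv_dx2
                ux = (u[i + 1] - u[i - 1]) * inv_2dx
        g[i] = k1 * rho[i] - k2 * lap + 0.5 * alpha * rho[i] * rho[i] - nu * ux


@njit(cache=True)
def _diff(f, dx, forward, periodic, out):
    n = f.shape[0]
    inv_dx = 1.0 / dx
    if forward:
        for i in range(n - 1):
            out[i] = (f[i + 1] - f[i]) * inv_dx
        out[n - 1] = (f[0] - f[n - 1]) * inv_dx if periodic else (f[n - 1] - f[n - 2]) * inv_dx
    else:
        for i in range(n - 1, 0, -1):
            out[i] = (f[i] - f[i - 1]) * inv_dx
        out[0] = (f[0] - f[n - 1]) * inv_dx if periodic else (f[1] - f[0]) * inv_dx


@njit(cache=True)
def _step(rho, u, h, dt, dx, k1, k2, alpha, nu, bc_mode, sponge_mult,
          forward_first, g, d, rho_p, u_p):
    n = rho.shape[0]
    periodic = bc_mode == BC_PERIODIC
    c = np.sqrt(k1)
    # old boundary neighbourhood for the characteristic update
    rho0l, u0l, rho1l, u1l = rho[0], u[0], rho[1], u[1]
    rho0r, u0r, rho1r, u1r = rho[n - 1], u[n - 1], rho[n - 2], u[n - 2]

    # predictor
    _compute_g(rho, u, dx, k1, k2, alpha, nu, periodic, g)
    _diff(u, dx, forward_first, periodic, d)
    for i in range(n):
        rho_p[i] = rho[i] - dt * d[i]
    _diff(g, dx, forward_first, periodic, d)
    for i in range(n):
        u_p[i] = u[i] - dt * (d[i] - h[i])

    # corrector: opposite direction, same forcing realization
    _compute_g(rho_p, u_p, dx, k1, k2, alpha, nu, periodic, g)
    _diff(u_p, dx, not forward_first, periodic, d)
    for i in range(n):
        rho[i] = 0.5 * (rho[i] + rho_p[i] - dt * d[i])
    _diff(g, dx, not forward_first, periodic, d)
    for i in range(n):
        u[i] = 0.5 * (u[i] + u_p[i] - dt * (d[i] - h[i]))

    if bc_mode == BC_SPONGE:
        for i in range(n):
            m = sponge_mult[i]
            if m != 1.0:
                rho[i] *= m
                u[i] *= m
    elif bc_mode == BC_CHARACTERISTIC:
        lam = c * dt / dx
        # left: outgoing w- = u - c rho advects at speed -c
        wm0 = u0l - c * rho0l
        wm1 = u1l - c * rho1l
        wm = wm0 + lam * (wm1 - wm0)
        rho[0] = -wm / (2.0 * c)
        u[0] = 0.5 * wm
        # right: outgoing w+ = u + c rho advects at speed +c
        wp0 = u0r + c * rho0r
        wp1 = u1r + c * rho1r
        wp = wp0 - lam * (wp0 - wp1)
        rho[n - 1] = wp / (2.0 * c)
        u[n - 1] = 0.5 * wp


@njit(cache=True)
def run_chunk(rho, u, n_chunk, h_block, use_noise, step0, dt, dx,
              k1, k2, alpha, nu, bc_mode, sponge_mult):
    """Advance ``n_chunk`` steps in place.

    ``h_block`` holds one row of forcing per step when ``use_noise``
    (row j is used, in full, by both MacCormack stages of step j);
    otherwise a single zero row is reused.  ``step0`` fixes the
    direction parity so alternation survives chunking.  Returns False
    if the fields went non-finite.
    """
    n = rho.shape[0]
    g = np.empty(n)
    d = np.empty(n)
    rho_p = np.empty(n)
    u_p = np.empty(n)
    for j in range(n_chunk):
        h = h_block[j] if use_noise else h_block[0]
        forward_first = ((step0 + j) % 2) == 0
        _step(rho, u, h, dt, dx, k1, k2, alpha, nu, bc_mode, sponge_mult,
              forward_first, g, d, rho_p, u_p)
    return np.isfinite(rho).all() and np.isfinite(u).all()
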