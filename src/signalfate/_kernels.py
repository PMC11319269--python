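"""Compiled inner loops for the population algorithm.

These kernels advance thousands of independent determinant switches (and,
in co-evolving mode, the stochastic signal lattice) by fixed-step
tau-leaping.  They are implementation details of :mod:`population_model`;
the generic, exact engine lives in :mod:`stochastic_kinetics`.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["determinant_leap", "signal_leap", "rk4_descend"]


@njit(cache=True, inline="always")
def _hillpow(x, n):
    """x**n with a fast path for the common integer Hill coefficients."""
    if n == 4.0:
        x2 = x * x
        return x2 * x2
    if n == 2.0:
        return x * x
    return x ** n


@njit(cache=True)
def determinant_leap(X, Y, AX, AY, n, bn, k1, k2, g1, g2,
                     omega, t_total, dt, seed):
    """Fixed-step tau-leap of the four determinant reactions per site.

    X, Y are flat int64 copy-number arrays; AX, AY the per-site
    self-activation rates.  Concentrations are counts/omega.  In-place.
    """
    np.random.seed(seed)
    m = X.size
    n_steps = int(np.ceil(t_total / dt))
    for _ in range(n_steps):
        for i in range(m):
            x = X[i] / omega
            y = Y[i] / omega
            xn = _hillpow(x, n)
            yn = _hillpow(y, n)
            px = (AX[i] * xn / (bn + xn) + k1 * bn / (bn + yn)) * omega
            py = (AY[i] * yn / (bn + yn) + k2 * bn / (bn + xn)) * omega
            X[i] += np.random.poisson(px * dt) - np.random.poisson(g1 * X[i] * dt)
            Y[i] += np.random.poisson(py * dt) - np.random.poisson(g2 * Y[i] * dt)
            if X[i] < 0:
                X[i] = 0
            if Y[i] < 0:
                Y[i] = 0


@njit(cache=True)
def signal_leap(SU, SV, A, B, C, gamma, d_eff, h, su_max,
                omega, t_total, dt, seed):
    """Fixed-step tau-leap of one signal channel on the lattice.

    SU, SV are 2-D int64 count arrays (in-place).  Kinetic events follow the
    reaction table with the confinement cap on s_u; diffusion hops fire per
    neighbor direction at 1/h^2 (activator) and d/h^2 (inhibitor) per
    molecule, with reflective edges (no hop channel across the boundary).
    """
    np.random.seed(seed)
    nr, nc = SU.shape
    cap = int(round(su_max * omega))
    ku = dt / (h * h)
    kv = dt * d_eff / (h * h)
    n_steps = int(np.ceil(t_total / dt))
    for _ in range(n_steps):
        dSU = np.zeros((nr, nc), dtype=np.int64)
        dSV = np.zeros((nr, nc), dtype=np.int64)
        for r in range(nr):
            for c in range(nc):
                su = SU[r, c] / omega
                sv = SV[r, c] / omega
                # kinetics (rows 1, 2, 4, 5)
                if SU[r, c] < cap:
                    dSU[r, c] += np.random.poisson(gamma * (A * su + C) * omega * dt)
                if SU[r, c] > 0:
                    dSU[r, c] -= np.random.poisson(gamma * sv * omega * dt)
                dSV[r, c] += np.random.poisson(gamma * B * su * omega * dt)
                if SV[r, c] > 0:
                    dSV[r, c] -= np.random.poisson(gamma * (sv + 1.0) * omega * dt)
                # diffusion hops (rows 3, 6)
                for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
                    r2, c2 = r + dr, c + dc
                    if r2 < 0 or r2 >= nr or c2 < 0 or c2 >= nc:
                        continue
                    hop = np.random.poisson(SU[r, c] * ku)
                    if hop > SU[r, c]:
                        hop = SU[r, c]
                    dSU[r, c] -= hop
                    dSU[r2, c2] += hop
                    hop = np.random.poisson(SV[r, c] * kv)
                    if hop > SV[r, c]:
                        hop = SV[r, c]
                    dSV[r, c] -= hop
                    dSV[r2, c2] += hop
        for r in range(nr):
            for c in range(nc):
                SU[r, c] += dSU[r, c]
                SV[r, c] += dSV[r, c]
                if SU[r, c] < 0:
                    SU[r, c] = 0
                elif SU[r, c] > cap:
                    SU[r, c] = cap
                if SV[r, c] < 0:
                    SV[r, c] = 0


@njit(cache=True, inline="always")
def _switch_dx(x, y, ax, ay, n, bn, k1, k2, g1, g2):
    xn = _hillpow(max(x, 0.0), n)
    yn = _hillpow(max(y, 0.0), n)
    dx = ax * xn / (bn + xn) + k1 * bn / (bn + yn) - g1 * x
    dy = ay * yn / (bn + yn) + k2 * bn / (bn + xn) - g2 * y
    return dx, dy


@njit(cache=True)
def _rk4_descend_core(x, y, ax, ay, n, bn, k1, k2, g1, g2, t_total, dt):
    m = x.size
    n_steps = int(np.ceil(t_total / dt))
    for i in range(m):
        xi, yi = x[i], y[i]
        for _ in range(n_steps):
            k1x, k1y = _switch_dx(xi, yi, ax[i], ay[i], n, bn, k1, k2, g1, g2)
            k2x, k2y = _switch_dx(xi + 0.5 * dt * k1x, yi + 0.5 * dt * k1y,
                                  ax[i], ay[i], n, bn, k1, k2, g1, g2)
            k3x, k3y = _switch_dx(xi + 0.5 * dt * k2x, yi + 0.5 * dt * k2y,
                                  ax[i], ay[i], n, bn, k1, k2, g1, g2)
            k4x, k4y = _switch_dx(xi + dt * k3x, yi + dt * k3y,
                                  ax[i], ay[i], n, bn, k1, k2, g1, g2)
            xi += dt / 6.0 * (k1x + 2 * k2x + 2 * k3x + k4x)
            yi += dt / 6.0 * (k1y + 2 * k2y + 2 * k3y + k4y)
            if xi < 0.0:
                xi = 0.0
            if yi < 0.0:
                yi = 0.0
            # settled: negligible motion relative to the degradation scale
            if abs(k1x) + abs(k1y) < 1e-9 * (1.0 + xi + yi):
                break
        x[i] = xi
        y[i] = yi


def rk4_descend(x, y, ax, ay, n, bn, k1, k2, g1, g2, t_total=40.0, dt=0.1):
    """Deterministic descent of the switch to its attractor (classical RK4,
    per site, with early exit once settled).  dt = 0.1 is well inside the
    stability bound: the stiffest local rate is ~alpha_max n / (4 beta)
    ~ 10 per time unit at alpha ~ 430."""
    x = np.ascontiguousarray(x, dtype=np.float64).copy()
    y = np.ascontiguousarray(y, dtype=np.float64).copy()
    _rk4_descend_core(x, y,
                      np.ascontiguousarray(ax, dtype=np.float64),
                      np.ascontiguousarray(ay, dtype=np.float64),
                      float(n), float(bn), float(k1), float(k2),
                      float(g1), float(g2), float(t_total), float(dt))
    return x, y
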