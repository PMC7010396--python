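"""Closed-form solution of the vertical (momentum) dynamics.

In sub-Riemannian arclength ``t`` the momenta obey

    h1' = -h2 h3,   h2' = h1 h3 / xi^2,   h3' = (1 - 1/xi^2) h1 h2,

which, in the half-angle variables ``C = cos(beta/2) = h1/xi``,
``S = sin(beta/2) = h2``, ``c = 2 h3 / xi``, is the mathematical pendulum
``beta'' = -r sin beta`` with ``r = 1/xi^2 - 1``.  All regimes (oscillation,
rotation, separatrix, the linear case r = 0, and r < 0 via the symmetry
``beta -> beta + pi, r -> -r``) are solved with Jacobi elliptic functions.
"""

from __future__ import annotations

import numpy as np
from scipy.special import ellipj, ellipk, ellipkinc

__all__ = ["pendulum_rhs", "solve_pendulum_cs", "momenta_closed_form_t"]

_SEPARATRIX_TOL = 1e-12


def pendulum_rhs(beta: float, c: float, r: float) -> tuple[float, float]:
    """Time derivative (beta_dot, c_dot) = (c, -r sin beta)."""
    return float(c), float(-r * np.sin(beta))


def solve_pendulum_cs(r, C0, S0, c0, t):
    """Closed-form (C, S, c)(t) of the half-angle pendulum system

        C' = -(c/2) S,   S' = (c/2) C,   c' = -2 r S C,

    for r >= 0, with C^2 + S^2 = 1.  Returns arrays matching ``t``.
    """
    if r < 0.0:
        raise ValueError("solve_pendulum_cs requires r >= 0; use the beta+pi symmetry")
    t = np.atleast_1d(np.asarray(t, dtype=float))
    if r == 0.0:
        phi = np.arctan2(S0, C0) + 0.5 * c0 * t
        return np.cos(phi), np.sin(phi), np.full_like(t, c0)

    w = np.sqrt(r)
    k2 = S0 * S0 + c0 * c0 / (4.0 * r)  # pendulum energy parameter

    if abs(k2 - 1.0) < _SEPARATRIX_TOL:
        return _separatrix(w, C0, S0, c0, t)
    if k2 < 1.0:
        return _oscillation(w, k2, C0, S0, c0, t)
    return _rotation(w, k2, C0, S0, c0, t)


def _oscillation(w, k2, C0, S0, c0, t):
    # S = k sn(w t + p0 | k^2), C = dn, c = 2 k w cn   (C keeps its sign)
    k = np.sqrt(k2)
    flip = 1.0
    if C0 < 0.0:  # solution symmetry (C,S,c) -> (-C,-S,c)
        C0, S0, flip = -C0, -S0, -1.0
    p0 = ellipkinc(np.arcsin(np.clip(S0 / k, -1.0, 1.0)), k2)
    if c0 < 0.0:
        p0 = 2.0 * ellipk(k2) - p0
    sn, cn, dn, _ = ellipj(w * t + p0, k2)
    return flip * dn, flip * k * sn, 2.0 * k * w * cn


def _rotation(w, k2, C0, S0, c0, t):
    # S = sn(v | 1/k^2), C = cn, c = 2 sgn(c0) w k dn,  v = sgn(c0) w k t + u0
    m = 1.0 / k2
    Om = w * np.sqrt(k2)
    sgn = 1.0 if c0 > 0.0 else -1.0
    u0 = ellipkinc(np.arcsin(np.clip(S0, -1.0, 1.0)), m)
    if C0 < 0.0:
        u0 = 2.0 * ellipk(m) - u0
    sn, cn, dn, _ = ellipj(sgn * Om * t + u0, m)
    return cn, sn, 2.0 * sgn * Om * dn


def _separatrix(w, C0, S0, c0, t):
    if c0 == 0.0 and abs(C0) < 1e-15:
        # unstable equilibrium (S, c) = (+-1, 0)
        one = np.ones_like(t)
        return C0 * one, S0 * one, c0 * one
    flip = 1.0
    if C0 < 0.0:
        C0, S0, flip = -C0, -S0, -1.0
    sgn = 1.0 if c0 > 0.0 else (-1.0 if c0 < 0.0 else 1.0)
    v = sgn * w * t + np.arctanh(np.clip(S0, -1.0 + 1e-16, 1.0 - 1e-16))
    sech = 1.0 / np.cosh(v)
    return flip * sech, flip * np.tanh(v), 2.0 * sgn * w * sech


def momenta_closed_form_t(xi, h0, t):
    """Closed-form momenta (h1, h2, h3)(t) for initial momentum ``h0``.

    Handles all stiffness regimes; for xi > 1 (r < 0) the pendulum symmetry
    ``beta -> beta + pi`` maps onto the solved case r > 0.
    """
    h10, h20, h30 = (float(v) for v in h0)
    r = 1.0 / xi**2 - 1.0
    C0, S0, c0 = h10 / xi, h20, 2.0 * h30 / xi
    if r >= 0.0:
        C, S, c = solve_pendulum_cs(r, C0, S0, c0, t)
    else:
        # (C~, S~) = (-S, C) solves the pendulum with r~ = -r
        Ct, St, c = solve_pendulum_cs(-r, -S0, C0, c0, t)
        C, S = St, -Ct
    return xi * C, S, xi * c / 2.0
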