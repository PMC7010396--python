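"""Sub-Riemannian geodesics of the uniform-cost problem on SO(3).

The normal Pontryagin extremals of the length functional
``int C sqrt(xi^2 u1^2 + u2^2) dt`` with controls ``u1`` (spatial, along X1)
and ``u2`` (angular, along X2) are driven by the Hamiltonian
``H = (h1^2/xi^2 + h2^2)/2`` with left-invariant momenta ``h_i``.  On
unit-speed geodesics ``2H = 1`` and the Casimir ``M^2 = h1^2+h2^2+h3^2``
are conserved.

Closed forms used here:

* vertical dynamics in SR arclength ``t``: Jacobi-elliptic pendulum
  solutions (:mod:`so3track.pendulum`);
* vertical dynamics in spherical arclength ``s``: elementary
  cosh/sinh (or linear for xi = 1) in ``chi = sqrt(xi^2 - 1)``
  (principal complex root for xi < 1);
* horizontal dynamics: the spatial momentum vector
  ``m = R(t) p(t)`` with ``p = (h2, -h1, h3)`` is a constant of motion,
  which reduces the rotation to an explicit algebraic frame plus a single
  quadrature for the rotation angle about ``m`` -- the same
  one-quadrature structure as the spherical-arclength solution, and, in
  the elliptic regime, an explicit incomplete-elliptic-integral formula.

A cusp of the spherical projection occurs where the spatial control
``u1 = h1/xi^2`` changes sign; the first cusp arclength ``s_max`` is the
minimal positive root of ``h1(s) = 0`` and has a closed form via the
complex logarithm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import cumulative_trapezoid, quad, solve_ivp
from scipy.optimize import brentq
from scipy.special import ellipkinc, elliprf, elliprj

from .pendulum import momenta_closed_form_t, pendulum_rhs
from .so3core import GroupPoint, chart_from_matrix, rotation_matrix

__all__ = [
    "ModelParams",
    "Momentum",
    "PendulumState",
    "GeodesicPath",
    "CuspError",
    "classify_case",
    "pendulum_dynamics",
    "exponential_map",
    "geodesic_closed_form_t",
    "closed_form_path_t",
    "vertical_solution_s",
    "cusp_arclength_smax",
    "cuspless_geodesic_s",
    "cuspless_path_s",
    "t_of_s",
    "geodesic_curvature_gauss_bonnet",
    "wavefront",
]

_H_TOL = 1e-9


class CuspError(ValueError):
    """Requested evaluation past (or at) the first cusp."""


@dataclass(frozen=True)
class ModelParams:
    """Stiffness parameter xi > 0 of the bending functional.

    ``chi = sqrt(xi^2 - 1)`` (principal root: imaginary for xi < 1) selects
    the elliptic (xi < 1), linear (xi = 1) or hyperbolic (xi > 1) regime.
    """

    xi: float = 1.0

    def __post_init__(self):
        if self.xi <= 0.0:
            raise ValueError("xi must be positive")

    @property
    def chi(self) -> complex:
        return complex(np.sqrt(complex(self.xi**2 - 1.0)))


@dataclass(frozen=True)
class Momentum:
    h1: float
    h2: float
    h3: float

    def as_array(self) -> np.ndarray:
        return np.array([self.h1, self.h2, self.h3])

    def hamiltonian(self, params: ModelParams) -> float:
        return 0.5 * (self.h1**2 / params.xi**2 + self.h2**2)

    def casimir_sq(self) -> float:
        return self.h1**2 + self.h2**2 + self.h3**2

    @classmethod
    def unit_speed(cls, params: ModelParams, beta: float, h3: float) -> "Momentum":
        """Momentum on the unit-speed cylinder 2H = 1, parameterized by the
        pendulum angle beta: h1 = xi cos(beta/2), h2 = sin(beta/2)."""
        return cls(params.xi * np.cos(beta / 2.0), np.sin(beta / 2.0), h3)


@dataclass(frozen=True)
class PendulumState:
    """Pendulum coordinates (beta, c) with r = 1/xi^2 - 1."""

    beta: float
    c: float
    r: float

    @classmethod
    def from_momentum(cls, h: Momentum, params: ModelParams) -> "PendulumState":
        beta = 2.0 * np.arctan2(h.h2, h.h1 / params.xi)
        return cls(beta, 2.0 * h.h3 / params.xi, 1.0 / params.xi**2 - 1.0)

    def to_momentum(self, params: ModelParams) -> Momentum:
        return Momentum(
            params.xi * np.cos(self.beta / 2.0),
            np.sin(self.beta / 2.0),
            params.xi * self.c / 2.0,
        )


@dataclass
class GeodesicPath:
    """Sampled geodesic: chart states, momenta, controls and parameter values.

    ``param_kind`` is one of ``sr_arclength_t`` | ``spherical_arclength_s`` |
    ``normalized_tau``.  ``states`` keeps *unwrapped* chart coordinates so
    finite differencing along the path stays continuous; the ``points``
    property wraps them into :class:`GroupPoint` instances.
    """

    states: np.ndarray  # (n, 3)
    momenta: np.ndarray  # (n, 3)
    param_kind: str
    param_values: np.ndarray  # (n,)
    controls: np.ndarray  # (n, 2)
    xi: float
    chart_exit: bool = False
    extras: dict = field(default_factory=dict)

    def __post_init__(self):
        dp = np.diff(self.param_values)
        if self.param_values[0] != 0.0 or (len(dp) and dp.min() <= 0.0):
            raise ValueError("param_values must strictly increase from 0")

    @property
    def points(self) -> list[GroupPoint]:
        return [GroupPoint(*row) for row in self.states]

    def sphere_curve(self) -> np.ndarray:
        """Spherical projection n = (cos x cos y, cos x sin y, sin x), (n, 3)."""
        x, y = self.states[:, 0], self.states[:, 1]
        cx = np.cos(x)
        return np.column_stack([cx * np.cos(y), cx * np.sin(y), np.sin(x)])


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def classify_case(params: ModelParams, M: float, rtol: float = 1e-12) -> str:
    """Phase-portrait type of the vertical dynamics for Casimir value M >= 0."""
    if M < 0.0:
        raise ValueError("M must be nonnegative")
    xi = params.xi
    M2, xi2 = M * M, xi * xi

    def eq(a, b):
        return abs(a - b) <= rtol * max(1.0, abs(a), abs(b))

    if xi < 1.0:
        if eq(M2, xi2):
            return "equilibrium_point"
        if M2 > xi2:
            return "elliptic"
        return "no_solution"
    if eq(xi, 1.0):
        if eq(M, 1.0):
            return "line_segment"
        if M2 > xi2:
            return "linear"
        return "no_solution"
    if eq(M2, xi2):
        return "crossing_segments"
    if M > 1.0:
        return "hyperbolic"
    return "no_solution"


def pendulum_dynamics(state: PendulumState, params: ModelParams | None = None):
    """(beta_dot, c_dot) of the mathematical-pendulum form of the vertical part."""
    return pendulum_rhs(state.beta, state.c, state.r)


# ---------------------------------------------------------------------------
# Hamiltonian flow (ODE route -- also the oracle for the closed forms)
# ---------------------------------------------------------------------------

def _full_rhs(t, z, xi):
    x, y, th, h1, h2, h3 = z
    u1 = h1 / xi**2
    u2 = h2
    cx = np.cos(x)
    return [
        u1 * np.cos(th),
        -u1 * np.sin(th) / cx,
        u1 * np.tan(x) * np.sin(th) + u2,
        -h2 * h3,
        h1 * h3 / xi**2,
        (1.0 - 1.0 / xi**2) * h1 * h2,
    ]


def _check_unit_speed(h0: Momentum, params: ModelParams):
    H = h0.hamiltonian(params)
    if abs(2.0 * H - 1.0) > _H_TOL:
        raise ValueError(f"momentum not on the unit-speed cylinder: 2H = {2*H:.3e}")


def exponential_map(
    h0: Momentum,
    params: ModelParams,
    T: float,
    n_steps: int = 100,
    rtol: float = 1e-10,
    atol: float = 1e-10,
) -> GeodesicPath:
    """Integrate the PMP Hamiltonian system from the identity.

    Adaptive Runge-Kutta (DOP853).  Stops early with ``chart_exit=True`` if
    the latitude reaches the chart singularity |x| = pi/2.
    """
    _check_unit_speed(h0, params)
    if T <= 0.0:
        raise ValueError("T must be positive")
    xi = params.xi

    def exit_event(t, z, xi):
        return np.pi / 2 - 1e-6 - abs(z[0])

    exit_event.terminal = True
    ts = np.linspace(0.0, T, n_steps + 1)
    sol = solve_ivp(
        _full_rhs,
        (0.0, T),
        [0.0, 0.0, 0.0, h0.h1, h0.h2, h0.h3],
        t_eval=ts,
        args=(xi,),
        method="DOP853",
        rtol=rtol,
        atol=atol,
        events=exit_event,
    )
    states = sol.y[:3].T.copy()
    momenta = sol.y[3:].T.copy()
    controls = np.column_stack([momenta[:, 0] / xi**2, momenta[:, 1]])
    return GeodesicPath(
        states=states,
        momenta=momenta,
        param_kind="sr_arclength_t",
        param_values=sol.t.copy(),
        controls=controls,
        xi=xi,
        chart_exit=bool(sol.status == 1),
    )


# ---------------------------------------------------------------------------
# closed forms: reconstruction from the conserved spatial momentum
# ---------------------------------------------------------------------------

def _body_momentum(h):
    """p = (h2, -h1, h3): components of the momentum in the fixed so(3) basis."""
    h1, h2, h3 = h
    return np.array([h2, -h1, h3])


def _section_frame(p, M):
    """Orthonormal frame [E1 E2 E3] with E3 = p/M, section vector e2.

    Defined whenever p is not parallel to e2, i.e. away from the
    great-circle (meridian) momenta h2 = h3 = 0.
    """
    n = p / M
    u = np.array([0.0, 1.0, 0.0]) - n[1] * n
    w = np.linalg.norm(u)
    if w < 1e-14:
        raise ValueError("section frame singular (pure great-circle momentum)")
    E1 = u / w
    E2 = np.cross(n, E1)
    return np.column_stack([E1, E2, n])


def _rot_z(a):
    ca, sa = np.cos(a), np.sin(a)
    return np.array([[ca, -sa, 0.0], [sa, ca, 0.0], [0.0, 0.0, 1.0]])


def _is_meridian(h2_0, h3_0, tol=1e-12):
    return abs(h2_0) < tol and abs(h3_0) < tol


def _meridian_states(angles):
    """Chart states of the great circle through e with tangent X1: the
    latitude folds past the pole (y and theta flip by pi there)."""
    states = np.empty((len(angles), 3))
    for i, a in enumerate(angles):
        ca, sa = np.cos(a), np.sin(a)
        states[i] = (np.arctan2(sa, abs(ca)), 0.0 if ca >= 0 else np.pi,
                     0.0 if ca >= 0 else np.pi)
    return states


def _reconstruct_R(h0_arr, h_t_arr, alpha):
    """R = E(0) Z(alpha) E(t)^T mapping body momentum p(t) to the fixed m."""
    M = np.linalg.norm(_body_momentum(h0_arr))
    E0 = _section_frame(_body_momentum(h0_arr), M)
    Et = _section_frame(_body_momentum(h_t_arr), M)
    return E0 @ _rot_z(alpha) @ Et.T


def geodesic_closed_form_t(h0: Momentum, params: ModelParams, t: float) -> GroupPoint:
    """Closed-form evaluation of the geodesic at SR arclength ``t``."""
    path = closed_form_path_t(h0, params, float(t), n_steps=1)
    return GroupPoint(*path.states[-1])


def closed_form_path_t(
    h0: Momentum, params: ModelParams, T: float, n_steps: int = 100
) -> GeodesicPath:
    """Closed-form geodesic sampled at ``n_steps + 1`` uniform SR arclengths.

    Vertical part: Jacobi-elliptic pendulum solution; horizontal part:
    momentum-frame reconstruction with the rotation angle

        alpha(t) = int_0^t [ 1/M - J h1(tau)^2 / (xi^2 M (M^2 - h1(tau)^2)) ] dtau,

    where ``J = h3^2 - (xi^2 - 1) h2^2`` is a constant of motion.
    """
    _check_unit_speed(h0, params)
    if T < 0.0:
        raise ValueError("T must be nonnegative")
    xi = params.xi
    ts = np.linspace(0.0, T, n_steps + 1) if T > 0.0 else np.array([0.0])

    if _is_meridian(h0.h2, h0.h3):
        u1 = h0.h1 / xi**2  # = +-1/xi
        states = _meridian_states(u1 * ts)
        momenta = np.tile(h0.as_array(), (len(ts), 1))
        controls = np.column_stack([np.full_like(ts, u1), np.zeros_like(ts)])
        return GeodesicPath(states, momenta, "sr_arclength_t", ts, controls, xi)

    M = np.sqrt(h0.casimir_sq())
    J = h0.h3**2 - (xi**2 - 1.0) * h0.h2**2

    h1s, h2s, h3s = momenta_closed_form_t(xi, h0.as_array(), ts)

    def alpha_rate(tau):
        h1 = float(momenta_closed_form_t(xi, h0.as_array(), tau)[0][0])
        return 1.0 / M - J * h1**2 / (xi**2 * M * (M**2 - h1**2))

    alpha = _cumulative_quad(alpha_rate, ts)

    states = np.empty((len(ts), 3))
    for i in range(len(ts)):
        R = _reconstruct_R(h0.as_array(), (h1s[i], h2s[i], h3s[i]), alpha[i])
        g = chart_from_matrix(R)
        states[i] = (g.x, g.y, g.theta)
    states = _unwrap_states(states)
    momenta = np.column_stack([h1s, h2s, h3s])
    controls = np.column_stack([h1s / xi**2, h2s])
    return GeodesicPath(states, momenta, "sr_arclength_t", ts, controls, xi)


def _cumulative_quad(f, ts, tol=1e-11):
    """Cumulative integral of smooth f over the sample points ts (adaptive)."""
    out = np.zeros(len(ts))
    for i in range(1, len(ts)):
        val, _ = quad(f, ts[i - 1], ts[i], epsabs=tol, epsrel=tol, limit=200)
        out[i] = out[i - 1] + val
    return out


def _unwrap_states(states):
    states = states.copy()
    states[:, 1] = np.unwrap(states[:, 1])
    states[:, 2] = np.unwrap(states[:, 2])
    return states


# ---------------------------------------------------------------------------
# spherical-arclength parameterization (cuspless geodesics)
# ---------------------------------------------------------------------------

def vertical_solution_s(h2_0: float, h3_0: float, params: ModelParams, s):
    """Momenta at spherical arclength(s) ``s``.

        h2(s) = h2(0) cosh(s chi) + (h3(0)/chi) sinh(s chi)
        h3(s) = h3(0) cosh(s chi) + chi h2(0) sinh(s chi)
        h1(s) = xi sqrt(1 - h2(s)^2)

    with the linear branch h2 = h2(0) + h3(0) s, h3 = h3(0) for xi = 1.
    Raises :class:`CuspError` if |h2(s)| > 1 (h1 would be imaginary).
    """
    if abs(h2_0) > 1.0:
        raise ValueError("|h2(0)| must be <= 1")
    xi = params.xi
    s = np.asarray(s, dtype=float)
    scalar = s.ndim == 0
    s = np.atleast_1d(s)
    if xi == 1.0:
        h2 = h2_0 + h3_0 * s
        h3 = np.full_like(s, h3_0)
    else:
        chi = params.chi
        ch, sh = np.cosh(s * chi), np.sinh(s * chi)
        h2c = h2_0 * ch + (h3_0 / chi) * sh
        h3c = h3_0 * ch + chi * h2_0 * sh
        if max(np.abs(h2c.imag).max(), np.abs(h3c.imag).max()) > 1e-10:
            raise FloatingPointError("vertical solution lost realness")
        h2, h3 = h2c.real, h3c.real
    if np.any(np.abs(h2) > 1.0 + 1e-12):
        raise CuspError("|h2(s)| > 1: past the first cusp, h1 imaginary")
    h1 = xi * np.sqrt(np.clip(1.0 - h2 * h2, 0.0, None))
    if scalar:
        return Momentum(float(h1[0]), float(h2[0]), float(h3[0]))
    return np.column_stack([h1, h2, h3])


def cusp_arclength_smax(h2_0: float, h3_0: float, params: ModelParams) -> float:
    """First cusp arclength: minimal positive root of h1(s) = 0, or +inf.

    Closed form: with z = e^{s chi}, h2(s) = sigma (sigma = +-1) reduces to a
    quadratic whose roots are z = (sigma chi +- sqrt(kappa)) / (h2(0) chi + h3(0)),
    kappa = h3(0)^2 + (1 - h2(0)^2) chi^2; candidate arclengths follow from the
    complex logarithm (plus the real period 2 pi/|chi| in the elliptic case).
    The minimal verified positive candidate is returned; a bisection fallback
    guards against branch mistakes.
    """
    if abs(h2_0) >= 1.0:
        raise CuspError("immediate cusp: |h2(0)| = 1")
    xi = params.xi
    if xi == 1.0:
        if h3_0 == 0.0:
            return np.inf
        cands = [(sg - h2_0) / h3_0 for sg in (1.0, -1.0)]
        return min(c for c in cands if c > 0.0)

    chi = params.chi
    kappa = complex(h3_0**2 + (1.0 - h2_0**2) * chi**2)
    denom = h2_0 * chi + h3_0
    if abs(denom) < 1e-300:
        # h2(s) = h2_0 e^{-s chi}: |h2| <= |h2_0| < 1 for chi > 0; for the
        # elliptic case |h2| oscillates with amplitude |h2_0| < 1.
        return np.inf
    sqk = np.sqrt(kappa)
    candidates = []
    for sigma in (1.0, -1.0):
        for pm in (1.0, -1.0):
            z = (sigma * chi + pm * sqk) / denom
            if abs(z) < 1e-300:
                continue
            s0 = np.log(z) / chi
            candidates.append(s0)
    # in the elliptic case solutions recur with real period 2 pi / |chi|
    period = 2.0 * np.pi / abs(chi.imag) if xi < 1.0 else None
    real_cands = []
    for s0 in candidates:
        if abs(s0.imag) > 1e-9:
            continue
        sr = s0.real
        if period is not None:
            sr = sr - np.floor(sr / period) * period
            if sr < 1e-12:
                sr += period
            real_cands.append(sr)
        elif sr > 1e-12:
            real_cands.append(sr)
    real_cands = [s for s in real_cands if _h1_vanishes(h2_0, h3_0, params, s)]
    if not real_cands:
        return np.inf
    s_best = min(real_cands)
    # guard: verify by bisection that h1 does not vanish earlier
    s_bis = _smax_bisection(h2_0, h3_0, params, s_best)
    if s_bis is not None and s_bis < s_best - 1e-8:
        return s_bis
    return s_best


def _h2_abs_minus_1(h2_0, h3_0, params, s):
    xi = params.xi
    if xi == 1.0:
        h2 = h2_0 + h3_0 * s
    else:
        chi = params.chi
        h2 = (h2_0 * np.cosh(s * chi) + (h3_0 / chi) * np.sinh(s * chi)).real
    return abs(h2) - 1.0


def _h1_vanishes(h2_0, h3_0, params, s, tol=1e-8):
    return abs(_h2_abs_minus_1(h2_0, h3_0, params, s)) < tol


def _smax_bisection(h2_0, h3_0, params, s_hint, n_scan=4096):
    """Scan [0, s_hint] for an earlier sign change of 1 - |h2|."""
    ss = np.linspace(0.0, s_hint * (1.0 - 1e-12), n_scan)
    vals = np.array([_h2_abs_minus_1(h2_0, h3_0, params, s) for s in ss])
    idx = np.where(vals >= 0.0)[0]
    if len(idx) == 0:
        return None
    i = idx[0]
    if i == 0:
        return None
    return brentq(
        lambda s: _h2_abs_minus_1(h2_0, h3_0, params, s), ss[i - 1], ss[i],
        xtol=1e-12,
    )


def cuspless_geodesic_s(h2_0: float, h3_0: float, params: ModelParams, s: float) -> GroupPoint:
    """Closed-form cuspless geodesic point at spherical arclength ``s``."""
    path = cuspless_path_s(h2_0, h3_0, params, float(s), n_steps=1)
    return GroupPoint(*path.states[-1])


def cuspless_path_s(
    h2_0: float,
    h3_0: float,
    params: ModelParams,
    s_end: float,
    n_steps: int = 100,
    use_elliptic_fast_path: bool = True,
) -> GeodesicPath:
    """Cuspless geodesic sampled at uniform spherical arclengths in [0, s_end].

    The rotation-angle quadrature

        alpha(s) = int_0^s [ xi^2/(h1 M) - J h1 / (M (M^2 - h1^2)) ] dsigma

    has, in the elliptic regime (xi < 1, M > xi), the closed form
    ``alpha = M/(xi sqrt(1-xi^2)) [Delta F - Delta Pi]`` in incomplete
    elliptic integrals of the first and third kind (used as a fast path and
    cross-checked against quadrature in the tests).
    """
    if abs(h2_0) >= 1.0:
        raise CuspError("cuspless geodesic needs |h2(0)| < 1")
    if s_end < 0.0:
        raise ValueError("s_end must be nonnegative")
    smax = cusp_arclength_smax(h2_0, h3_0, params) if not _is_meridian(h2_0, h3_0) else np.inf
    if s_end > smax + 1e-10:
        raise CuspError(f"s_end = {s_end:.6g} exceeds first cusp s_max = {smax:.6g}")
    xi = params.xi
    ss = np.linspace(0.0, s_end, n_steps + 1) if s_end > 0.0 else np.array([0.0])

    if _is_meridian(h2_0, h3_0):
        states = _meridian_states(ss)
        momenta = np.tile([xi, 0.0, 0.0], (len(ss), 1))
        controls = np.column_stack([np.ones_like(ss), np.zeros_like(ss)])
        return GeodesicPath(states, momenta, "spherical_arclength_s", ss, controls, xi)

    h10 = xi * np.sqrt(1.0 - h2_0**2)
    h0_arr = np.array([h10, h2_0, h3_0])
    M = np.linalg.norm(h0_arr)
    J = h3_0**2 - (xi**2 - 1.0) * h2_0**2

    hs = vertical_solution_s(h2_0, h3_0, params, ss)
    h1s, h2s, h3s = hs[:, 0], hs[:, 1], hs[:, 2]

    # the elliptic fast path needs the oscillatory regime (modulus rho < 1)
    if use_elliptic_fast_path and xi < 1.0 and xi < M < 1.0:
        alpha = _alpha_elliptic_closed_form(h2_0, h3_0, xi, M, ss)
    else:
        def alpha_rate(sig):
            h = vertical_solution_s(h2_0, h3_0, params, np.atleast_1d(sig))
            h1 = max(h[0, 0], 1e-14)
            return xi**2 / (h1 * M) - J * h1 / (M * (M**2 - h1**2))

        alpha = _cumulative_quad(alpha_rate, ss)

    states = np.empty((len(ss), 3))
    for i in range(len(ss)):
        R = _reconstruct_R(h0_arr, (h1s[i], h2s[i], h3s[i]), alpha[i])
        g = chart_from_matrix(R)
        states[i] = (g.x, g.y, g.theta)
    states = _unwrap_states(states)
    momenta = np.column_stack([h1s, h2s, h3s])
    with np.errstate(divide="ignore"):
        kg = np.where(h1s > 0.0, xi**2 * h2s / np.where(h1s > 0, h1s, 1.0), np.inf)
    controls = np.column_stack([np.ones_like(ss), kg])  # d/ds controls: (1, k_g)
    return GeodesicPath(states, momenta, "spherical_arclength_s", ss, controls, xi)


def _alpha_elliptic_closed_form(h2_0, h3_0, xi, M, ss):
    """alpha(s) = M/(xi sqrt(1-xi^2)) [F(Psi,m) - Pi(n;Psi|m)]_{Psi0}^{Psi(s)}

    with h2 = rho sin(Psi), Psi(s) = s sqrt(1-xi^2) + Psi0,
    rho^2 = (M^2-xi^2)/(1-xi^2), m = rho^2, n = -xi^2 rho^2/(M^2-xi^2).
    """
    q = np.sqrt(1.0 - xi**2)
    rho2 = (M**2 - xi**2) / (1.0 - xi**2)
    rho = np.sqrt(rho2)
    psi0 = np.arctan2(h2_0, h3_0 / q)
    psi = ss * q + psi0
    m = rho2
    n = -(xi**2) * rho2 / (M**2 - xi**2)
    dF = ellipkinc(psi, m) - ellipkinc(psi0, m)
    dPi = _ellippi_inc(n, psi, m) - _ellippi_inc(n, psi0, m)
    return (M / (xi * q)) * (dF - dPi)


def _ellippi_inc(n, phi, m):
    """Incomplete elliptic integral of the third kind Pi(n; phi | m) for
    arbitrary real amplitude, via Carlson symmetric forms (n < 1 required)."""
    phi = np.atleast_1d(np.asarray(phi, dtype=float))
    k = np.round(phi / np.pi)
    phir = phi - k * np.pi  # in [-pi/2, pi/2]
    sp = np.sin(np.abs(phir))
    cp2 = 1.0 - sp**2
    q = 1.0 - m * sp**2
    base = sp * elliprf(cp2, q, np.ones_like(sp)) + (n / 3.0) * sp**3 * elliprj(
        cp2, q, np.ones_like(sp), 1.0 - n * sp**2
    )
    base = base * np.sign(phir)
    if np.any(k != 0):
        comp = elliprf(0.0, 1.0 - m, 1.0) + (n / 3.0) * elliprj(0.0, 1.0 - m, 1.0, 1.0 - n)
        base = base + 2.0 * k * comp
    return base


# ---------------------------------------------------------------------------
# reparameterization and curvature
# ---------------------------------------------------------------------------

def t_of_s(path: GeodesicPath, cost_values=None) -> np.ndarray:
    """SR arclength t(s) = int_0^s cost * sqrt(xi^2 + k_g^2) dsigma along an
    s-parameterized path (trapezoidal quadrature; cost defaults to 1).

    Equivalently dt/ds = xi^2 / h1; both routes agree on smooth samples.
    """
    if path.param_kind != "spherical_arclength_s":
        raise ValueError("t_of_s needs a spherical-arclength path")
    ss = path.param_values
    if cost_values is None:
        cost_values = np.ones_like(ss)
    cost_values = np.asarray(cost_values, dtype=float)
    h1, h2 = path.momenta[:, 0], path.momenta[:, 1]
    with np.errstate(divide="ignore"):
        kg = path.xi**2 * h2 / h1
    integrand = cost_values * np.sqrt(path.xi**2 + kg**2)
    integrand = np.where(np.isfinite(integrand), integrand, 0.0)
    return np.concatenate([[0.0], cumulative_trapezoid(integrand, ss)])


def geodesic_curvature_gauss_bonnet(sphere_curve, s_values) -> np.ndarray:
    """Geodesic curvature k_g(s) = n'' . (n x n') of a unit-speed sphere curve
    by central differences (endpoints copied from their neighbors)."""
    n = np.asarray(sphere_curve, dtype=float)
    s = np.asarray(s_values, dtype=float)
    if len(n) < 5:
        raise ValueError("need at least 5 samples for curvature estimation")
    h = np.diff(s)
    if not np.allclose(h, h[0], rtol=1e-6):
        raise ValueError("s_values must be uniformly spaced (resample first)")
    h = h[0]
    d1 = (n[2:] - n[:-2]) / (2.0 * h)
    d2 = (n[2:] - 2.0 * n[1:-1] + n[:-2]) / h**2
    kg_mid = np.einsum("ij,ij->i", d2, np.cross(n[1:-1], d1))
    return np.concatenate([[kg_mid[0]], kg_mid, [kg_mid[-1]]])


# ---------------------------------------------------------------------------
# wavefronts
# ---------------------------------------------------------------------------

def wavefront(
    params: ModelParams,
    T: float,
    n_beta: int = 64,
    n_c: int = 33,
    c_cap: float = 10.0,
    return_momenta: bool = False,
):
    """Endpoint cloud WF(T) of unit-speed geodesics of SR length T.

    Initial momenta sample the cylinder 2H = 1: beta(0) uniform on [0, 4 pi),
    c(0) on a symmetric grid in [-c_cap, c_cap].  Endpoints whose geodesic
    leaves the chart before time T are skipped.
    """
    if T <= 0.0:
        raise ValueError("T must be positive")
    xi = params.xi
    betas = np.linspace(0.0, 4.0 * np.pi, n_beta, endpoint=False)
    cs = np.linspace(-c_cap, c_cap, n_c)
    points, moms = [], []
    for b in betas:
        for c in cs:
            h0 = Momentum(xi * np.cos(b / 2.0), np.sin(b / 2.0), xi * c / 2.0)
            try:
                g = geodesic_closed_form_t(h0, params, T)
            except ValueError:
                continue
            points.append(g)
            moms.append(h0)
    if return_momenta:
        return points, moms
    return points
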