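"""Geodesic backtracking through the SR distance map and curvature read-out.

Once the distance map W from the seed is known, the globally optimal
geodesic to any endpoint is recovered by steepest descent: the momenta are
read from the map as ``h1 = X1(W), h2 = X2(W)`` (directional derivatives
along the left-invariant frame) and the backtracked curve solves

    gamma' = -(u1 X1 + u2 X2),   u1 = h1/(xi^2 C^2),  u2 = h2/C^2.

The geodesic curvature of the spherical projection follows directly from
the same derivatives: kappa_g = xi^2 X2(W)/X1(W); a sign change of X1(W)
(spatial control) marks a cusp.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .camera import CameraModel
from .geodesics import GeodesicPath
from .grid import ScalarField3D
from .eikonal import SolverParams
from .so3core import GroupPoint, frame, rotation_matrix, chart_from_matrix

__all__ = [
    "TrackResult",
    "BacktrackError",
    "backtrack",
    "curvature_from_W",
    "planar_curvature",
    "track_vessel",
]

CUSP_FLAG_RATIO = 0.05


class BacktrackError(RuntimeError):
    pass


@dataclass
class TrackResult:
    """Backtracked geodesic from seed to endpoint.

    ``path`` runs seed -> endpoint in normalized time tau in [0, 1];
    ``sr_length`` is W(endpoint), the data-driven SR length of the track.
    ``curvature_g`` holds the geodesic curvature kappa_g per sample
    (NaN where flagged cusp-suspect, see ``cusp_suspect``).
    """

    path: GeodesicPath
    sr_length: float
    curvature_g: np.ndarray
    cusp_suspect: np.ndarray
    planar_curvature: np.ndarray | None = None
    meta: dict = field(default_factory=dict)


def _frame_derivatives(W: ScalarField3D, x, y, th):
    """(X1 W, X2 W, X3 W) at a chart point from the order-3 interpolant."""
    grad = W.gradient_at(x, y, th)
    F = frame((x, y, th))  # rows X1, X2, X3 in (d/dx, d/dy, d/dtheta)
    return F @ grad


def backtrack(
    W: ScalarField3D,
    cost,
    endpoint: GroupPoint,
    params: SolverParams,
    step: float | None = None,
    max_steps: int | None = None,
    cuspless: bool = False,
) -> TrackResult:
    """Steepest-descent geodesic from ``endpoint`` back to the seed of W.

    Classical RK4 with fixed chart-arclength step (default: half the
    smallest grid spacing).  Stops on reaching the seed cell and appends
    the seed node.  Raises :class:`BacktrackError` on a stall (W failing to
    decrease over 10 consecutive steps) or when leaving the grid.

    ``cuspless=True`` forbids the reverse spatial control (clamps the
    backward X1 component so the forward track never reverses on the
    sphere).  Experimental: near genuine cusps the clamped field can
    stall.
    """
    g = W.grid
    xi = params.xi
    cost_f = _cost_lookup(cost)
    h_min = g.min_spacing()
    ds = 0.5 * h_min if step is None else float(step)
    Wend = float(W.interpolate(endpoint.x, endpoint.y, endpoint.theta))
    if not np.isfinite(Wend):
        raise BacktrackError("endpoint unreachable (infinite W)")
    if max_steps is None:
        max_steps = 40000

    seed = np.array(W.seed) if W.seed is not None else np.zeros(3)

    eps2 = params.eps**2

    def rhs(p):
        # steepest descent of the Riemannian approximation: the inverse
        # metric maps dW to (h1/xi^2) X1 + h2 X2 + (eps^2 h3/xi^2) X3 (over
        # C^2); the X3 term vanishes in the SR limit but recenters the
        # discrete path inside narrow cost valleys.  Chart-arclength steps
        # keep RK4 stable for any cost magnitude.
        x, y, th = p
        if abs(x) > g.x_cap:
            raise BacktrackError("backtracked path left the grid in x")
        d = _frame_derivatives(W, x, y, th)
        u1 = d[0] / xi**2
        if cuspless:
            u1 = max(u1, 0.0)  # forbid the reverse spatial control
        F = frame((x, y, th))
        v = u1 * F[0] + d[1] * F[1] + (eps2 * d[2] / xi**2) * F[2]
        nv = np.linalg.norm(v)
        if nv == 0.0:
            raise BacktrackError("vanishing descent direction")
        return -v / nv

    def near_seed(p):
        dy = (p[1] - seed[1] + np.pi) % (2 * np.pi) - np.pi
        dt_ = (p[2] - seed[2] + np.pi) % (2 * np.pi) - np.pi
        return np.sqrt((p[0] - seed[0]) ** 2 + dy**2 + dt_**2)

    pts = [np.array([endpoint.x, endpoint.y, endpoint.theta])]
    wvals = [Wend]
    stall = 0
    for _ in range(max_steps):
        p = pts[-1]
        k1 = rhs(p)
        k2 = rhs(p + 0.5 * ds * k1)
        k3 = rhs(p + 0.5 * ds * k2)
        k4 = rhs(p + ds * k3)
        p_new = p + (ds / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        w_new = float(W.interpolate(*p_new))
        pts.append(p_new)
        wvals.append(w_new)
        if near_seed(p_new) < 2.5 * h_min:
            break
        if w_new >= wvals[-2] - 1e-14:
            stall += 1
            if stall >= 10:
                raise BacktrackError(
                    f"stalled at W = {w_new:.4f} (flat or noisy distance map)"
                )
        else:
            stall = 0
    else:
        raise BacktrackError("backtracking did not reach the seed")

    if W.seed is not None:
        pts.append(np.array(W.seed))
        wvals.append(0.0)
    pts = np.array(pts[::-1])  # reversed: seed -> endpoint
    wvals = np.array(wvals[::-1])

    # normalized time tau in [0, 1]; strictly increasing via W values
    tau = wvals / max(Wend, 1e-300)
    tau = np.maximum.accumulate(tau)
    keep = np.concatenate([[True], np.diff(tau) > 1e-12])
    pts, tau, wvals = pts[keep], tau[keep], wvals[keep]
    tau[0], tau[-1] = 0.0, 1.0

    momenta = np.empty((len(pts), 3))
    controls = np.empty((len(pts), 2))
    for i, p in enumerate(pts):
        d = _frame_derivatives(W, *p)
        C = cost_f(*p)
        momenta[i] = d
        controls[i] = (d[0] / (xi**2 * C**2), d[1] / C**2)

    path = GeodesicPath(
        states=pts,
        momenta=momenta,
        param_kind="normalized_tau",
        param_values=tau,
        controls=controls,
        xi=xi,
        extras={"W_values": wvals},
    )
    kg, suspect = curvature_from_W(W, path, params)
    return TrackResult(
        path=path, sr_length=Wend, curvature_g=kg, cusp_suspect=suspect
    )


def curvature_from_W(W: ScalarField3D, path: GeodesicPath, params: SolverParams):
    """Geodesic curvature kappa_g = xi^2 X2(W)/X1(W) along the path.

    Samples with |X1(W)| below ``CUSP_FLAG_RATIO`` times the momentum norm
    are flagged cusp-suspect and reported as signed infinity."""
    kg = np.empty(len(path.states))
    suspect = np.zeros(len(path.states), dtype=bool)
    for i, p in enumerate(path.states):
        d = _frame_derivatives(W, *p)
        norm = np.hypot(d[0], d[1])
        if abs(d[0]) < CUSP_FLAG_RATIO * norm or norm == 0.0:
            suspect[i] = True
            kg[i] = np.inf if d[1] >= 0 else -np.inf
        else:
            kg[i] = params.xi**2 * d[1] / d[0]
    return kg, suspect


def planar_curvature(path: GeodesicPath, cam: CameraModel) -> np.ndarray:
    """Signed curvature of the flat-image projection Gamma = Pi(x, y).

    Finite differences with the parameterization-invariant formula
    kappa = (X' Y'' - Y' X'') / (X'^2 + Y'^2)^(3/2).
    """
    if len(path.states) < 5:
        raise ValueError("need at least 5 samples")
    X, Y = cam.project(path.states[:, 0], path.states[:, 1])
    u = path.param_values
    dX, dY = np.gradient(X, u), np.gradient(Y, u)
    d2X, d2Y = np.gradient(dX, u), np.gradient(dY, u)
    sp2 = dX**2 + dY**2
    if np.any(sp2 <= 1e-24):
        raise ValueError("degenerate spacing: consecutive projected points coincide")
    return (dX * d2Y - dY * d2X) / sp2**1.5


def _cost_lookup(cost):
    if cost is None:
        return lambda x, y, th: 1.0
    if hasattr(cost, "field"):
        cost = cost.field
    if isinstance(cost, ScalarField3D):
        return lambda x, y, th: float(cost.interpolate(x, y, th))
    raise TypeError("cost must be None, a CostField or a ScalarField3D")


# ---------------------------------------------------------------------------
# end-to-end vessel tracking
# ---------------------------------------------------------------------------

def track_vessel(
    image,
    seed_pt: GroupPoint,
    end_pt: GroupPoint,
    cfg,
    cuspless: bool = False,
) -> TrackResult:
    """Full pipeline: vesselness cost -> SR eikonal -> backtracking.

    ``image`` is an :class:`so3track.vesselness.Image2D` flat fundus-style
    image; ``cfg`` a :class:`so3track.config.RunConfig`.  The solver fixes
    its boundary condition at the identity, so the cost field is resampled
    under the left action taking ``seed_pt`` to e and the resulting path is
    mapped back.
    """
    from .config import RunConfig
    from .grid import ChartGrid
    from .eikonal import solve_eikonal
    from .vesselness import VesselnessParams, external_cost, vesselness

    if not isinstance(cfg, RunConfig):
        raise TypeError("cfg must be a RunConfig")
    cam = cfg.camera_model()
    grid = ChartGrid(nx=cfg.grid_nx, ny=cfg.grid_ny, nt=cfg.grid_nt, x_cap=cfg.x_cap)
    vp = VesselnessParams(
        beta=cfg.beta, c_resp=cfg.c_resp, scales=tuple(cfg.scales), lam=cfg.lam,
        normalize_vesselness=cfg.normalize_vesselness,
    )
    VF = vesselness(image, vp)

    R_seed = rotation_matrix(seed_pt)
    cost = external_cost(VF, image, cam, vp, grid, rotation=R_seed)

    sparams = SolverParams(xi=cfg.xi, eps=cfg.eps, scheme=cfg.scheme)
    W = solve_eikonal(cost, sparams, grid)

    end_shifted = chart_from_matrix(R_seed.T @ rotation_matrix(end_pt))
    result = backtrack(W, cost, end_shifted, sparams, cuspless=cuspless)

    # map the path back under the left action
    mapped = np.empty_like(result.path.states)
    for i, p in enumerate(result.path.states):
        gi = chart_from_matrix(R_seed @ rotation_matrix(GroupPoint(*_wrap_state(p))))
        mapped[i] = (gi.x, gi.y, gi.theta)
    mapped[:, 1] = np.unwrap(mapped[:, 1])
    mapped[:, 2] = np.unwrap(mapped[:, 2])
    result.path.states = mapped
    result.planar_curvature = planar_curvature(result.path, cam)
    result.meta.update({"seed": seed_pt, "endpoint": end_pt, "config": cfg})
    return result


def _wrap_state(p):
    x = float(np.clip(p[0], -np.pi / 2, np.pi / 2))
    return (x, p[1], p[2])
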