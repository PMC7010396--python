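"""Sub-Riemannian eikonal solver on the (x, y, theta) chart.

The SR distance map W solves ``sqrt((X1 W)^2/xi^2 + (X2 W)^2) = C`` with
``W(e) = 0`` in the viscosity sense.  Motion transverse to the distribution
(along X3) is forbidden; numerically it is penalized by the Riemannian
approximation with metric

    M_eps = Omega^T diag(C^2 xi^2, C^2, C^2 xi^2 / eps^2) Omega,

where Omega stacks the left-invariant coframe (omega^1, omega^2, omega^3)
in the fixed (dx, dy, dtheta) basis and ``eps`` (default 0.1) is the
anisotropy parameter.  The discrete solver is a monotone semi-Lagrangian
scheme (see :mod:`so3track._fm_kernels`) run either as causal fast
marching plus Gauss-Seidel polish, or as pure iterative sweeping.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _fm_kernels as fmk
from .grid import ChartGrid, ScalarField3D
from .so3core import GroupPoint

__all__ = ["SolverParams", "metric_matrix", "metric_field", "solve_eikonal", "level_set"]


@dataclass(frozen=True)
class SolverParams:
    """Eikonal solver parameters.

    xi: stiffness of the bending functional (weights spatial motion).
    eps: Riemannian anisotropy in (0, 1]; the SR limit is eps -> 0.
    scheme: 'anisotropic_fast_marching' (causal pass + label-correcting
        polish to the fixed point) or 'iterative_sweeping' (pure
        Gauss-Seidel with alternating orderings).
    seed_ball: 'auto' | 'on' | 'off'.  When the external cost is uniform
        the metric is left-invariant, so a small ball around the seed can
        be initialized exactly by sampling the group exponential map; this
        removes most of the source-singularity error of the grid scheme.
        'auto' enables it exactly in the uniform-cost case.
    """

    xi: float = 1.0
    eps: float = 0.1
    seed: GroupPoint = GroupPoint(0.0, 0.0, 0.0)
    scheme: str = "anisotropic_fast_marching"
    seed_ball: str = "auto"
    polish_sweeps: int = 12
    sweep_tol: float = 1e-4

    def __post_init__(self):
        if self.xi <= 0.0 or not (0.0 < self.eps <= 1.0):
            raise ValueError("require xi > 0 and eps in (0, 1]")
        if self.scheme not in ("anisotropic_fast_marching", "iterative_sweeping"):
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if self.seed_ball not in ("auto", "on", "off"):
            raise ValueError("seed_ball must be 'auto', 'on' or 'off'")


def metric_matrix(g: GroupPoint | tuple, C_val: float, params: SolverParams) -> np.ndarray:
    """Riemannian approximation metric M_eps at ``g`` (fixed chart basis)."""
    if isinstance(g, GroupPoint):
        x, th = g.x, g.theta
    else:
        x, _, th = (float(v) for v in g)
    Om = _coframe_stack(np.atleast_1d(x), np.atleast_1d(th))[0, 0]
    D = np.diag([params.xi**2, 1.0, params.xi**2 / params.eps**2])
    return float(C_val) ** 2 * Om.T @ D @ Om


def _coframe_stack(x, th):
    """Omega arrays, shape (len(x), len(th), 3, 3): rows omega^1..3."""
    cx, sx = np.cos(x)[:, None], np.sin(x)[:, None]
    ct, st = np.cos(th)[None, :], np.sin(th)[None, :]
    nxv, ntv = len(x), len(th)
    Om = np.zeros((nxv, ntv, 3, 3))
    Om[..., 0, 0] = np.broadcast_to(ct, (nxv, ntv))
    Om[..., 0, 1] = -cx * st
    Om[..., 1, 1] = np.broadcast_to(sx, (nxv, ntv))
    Om[..., 1, 2] = 1.0
    Om[..., 2, 0] = np.broadcast_to(st, (nxv, ntv))
    Om[..., 2, 1] = cx * ct
    return Om


def metric_field(grid: ChartGrid, params: SolverParams) -> np.ndarray:
    """M_eps (cost-free part, C = 1) at every (x, theta) node: (nx, nt, 3, 3)."""
    Om = _coframe_stack(grid.x_nodes, np.arange(grid.nt) * grid.ht)
    D = np.array([params.xi**2, 1.0, params.xi**2 / params.eps**2])
    return np.einsum("xtia,i,xtib->xtab", Om, D, Om)


_STENCIL = None


def _stencil():
    global _STENCIL
    if _STENCIL is None:
        _STENCIL = fmk.build_stencil()
    return _STENCIL


def _precompute_G0(grid: ChartGrid, params: SolverParams):
    offsets, tets, tets_of_offset, neg_index = _stencil()
    M0 = metric_field(grid, params)  # (nx, nt, 3, 3)
    h = np.array([grid.hx, grid.hy, grid.ht])
    V = offsets[tets] * h  # (48, 3verts, 3comp)
    Gfull = np.einsum("tka,xyab,tlb->xytkl", V, M0, V)  # (nx, nt, 48, 3, 3)
    iu = [(0, 0), (0, 1), (0, 2), (1, 1), (1, 2), (2, 2)]
    G0 = np.stack([Gfull[..., i, j] for i, j in iu], axis=-1)
    return np.ascontiguousarray(G0.reshape(-1, 6))


def solve_eikonal(
    cost,
    params: SolverParams,
    grid: ChartGrid,
    max_sweeps: int = 400,
    until_target: GroupPoint | None = None,
) -> ScalarField3D:
    """Distance map W from the seed, as the fixed point of the monotone
    semi-Lagrangian discretization of the Riemannian-approximated SR metric.

    ``cost`` is the lifted external cost: a CostField / ScalarField3D, an
    array of grid shape, or None for the uniform case C = 1.  Unreachable
    nodes get W = +inf.

    ``until_target`` stops the fast-marching pass once that chart point
    freezes (an approximation: the label-correcting polish is skipped, so
    the map is single-pass causal only; use for speed when only one
    endpoint matters).
    """
    C = _cost_values(cost, grid)
    if np.any(C <= 0.0):
        raise ValueError("external cost must be strictly positive")
    offsets, tets, tets_of_offset, neg_index = _stencil()
    G0 = _precompute_G0(grid, params)
    nx, ny, nt = grid.shape
    C2 = np.ascontiguousarray((C * C).reshape(-1))

    seed_idx = grid.nearest_node(params.seed.x, params.seed.y, params.seed.theta)
    seed_flat = (seed_idx[0] * ny + seed_idx[1]) * nt + seed_idx[2]

    uniform = bool(np.ptp(C) < 1e-12)
    use_ball = params.seed_ball == "on" or (params.seed_ball == "auto" and uniform)

    W = np.full(nx * ny * nt, fmk.BIG)
    if use_ball:
        _seed_ball_scatter(W, grid, params, seed_idx, float(C.flat[0]))
    # first shell: exact local Riemannian distance (frozen metric at neighbor)
    M0 = metric_field(grid, params)
    h = np.array([grid.hx, grid.hy, grid.ht])
    for o in offsets:
        jx = seed_idx[0] + o[0]
        if jx < 0 or jx >= nx:
            continue
        jy = (seed_idx[1] + o[1]) % ny
        jt = (seed_idx[2] + o[2]) % nt
        v = o * h
        M = M0[jx, jt] * C[jx, jy, jt] ** 2
        flat = (jx * ny + jy) * nt + jt
        W[flat] = min(W[flat], np.sqrt(v @ M @ v))
    W[seed_flat] = 0.0

    if params.scheme == "anisotropic_fast_marching":
        target_flat = -1
        if until_target is not None:
            ti = grid.nearest_node(until_target.x, until_target.y, until_target.theta)
            target_flat = (ti[0] * ny + ti[1]) * nt + ti[2]
        fmk.fast_march(W, C2, G0, offsets, tets, tets_of_offset, neg_index,
                       seed_flat, nx, ny, nt, target_flat)
        if target_flat < 0:
            # polish to the fixed point, processing in nearly-causal W order
            order = np.argsort(W, kind="stable").astype(np.int64)
            fmk.label_correct(W, C2, G0, offsets, tets, seed_flat, order,
                              nx, ny, nt, params.sweep_tol)
    else:
        fmk.gauss_seidel_sweeps(W, C2, G0, offsets, tets, seed_flat,
                                nx, ny, nt, max_sweeps, params.sweep_tol)

    W = W.reshape(grid.shape)
    W[W >= fmk.BIG / 2] = np.inf
    return ScalarField3D(values=W, grid=grid, seed=grid.node_coords(*seed_idx))


def _seed_ball_scatter(
    W,
    grid: ChartGrid,
    params: SolverParams,
    seed_idx,
    cost_value: float,
    T0: float | None = None,
    n_beta: int = 256,
    n_c: int = 161,
    c_cap: float = 16.0,
):
    """Initialize a ball around the seed with exact SR arrival times.

    For a uniform cost the metric is left-invariant, so the distance ball is
    the image of the group exponential map: all unit-speed geodesics are
    integrated (vectorized fixed-step RK4 over a dense momentum sample) up
    to time T0 and each grid node visited records the earliest arrival.
    Nearest-node scatter: the values carry an O(h) offset error but are a
    dramatically better start than a one-cell shell, since the grid scheme
    is least accurate where the characteristics bend near the source.
    """
    xi = params.xi
    nx, ny, nt = grid.shape
    if T0 is None:
        # cover the zone where characteristics bend strongly (radius ~0.5
        # in SR length), or a few cells on very coarse grids
        hmax = max(grid.hx, grid.hy, grid.ht)
        T0 = float(max(0.5, min(0.8, 8.0 * hmax)))
    x0, y0, t0 = grid.node_coords(*seed_idx)
    betas = np.linspace(0.0, 4.0 * np.pi, n_beta, endpoint=False)
    cs = np.linspace(-c_cap, c_cap, n_c)
    B, Cc = np.meshgrid(betas, cs, indexing="ij")
    z = np.zeros((6, B.size))
    z[0], z[1], z[2] = x0, y0, t0
    z[3] = xi * np.cos(B / 2.0).ravel()
    z[4] = np.sin(B / 2.0).ravel()
    z[5] = xi * Cc.ravel() / 2.0

    def rhs(z):
        x, y, th, h1, h2, h3 = z
        x = np.clip(x, -1.55, 1.55)
        u1 = h1 / xi**2
        cx = np.cos(x)
        return np.array(
            [
                u1 * np.cos(th),
                -u1 * np.sin(th) / cx,
                u1 * np.tan(x) * np.sin(th) + h2,
                -h2 * h3,
                h1 * h3 / xi**2,
                (1.0 - 1.0 / xi**2) * h1 * h2,
            ]
        )

    nsub = 60
    dt = T0 / nsub
    t = 0.0
    for _ in range(nsub):
        k1 = rhs(z)
        k2 = rhs(z + 0.5 * dt * k1)
        k3 = rhs(z + 0.5 * dt * k2)
        k4 = rhs(z + dt * k3)
        z = z + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        t += dt
        valid = np.abs(z[0]) < np.pi / 2 - 0.02
        ix = np.round((z[0] + grid.x_cap) / grid.hx).astype(np.int64)
        iy = np.round(np.mod(z[1], 2.0 * np.pi) / grid.hy).astype(np.int64) % ny
        it = np.round(np.mod(z[2], 2.0 * np.pi) / grid.ht).astype(np.int64) % nt
        ok = valid & (ix >= 0) & (ix < nx)
        flat = (ix[ok] * ny + iy[ok]) * nt + it[ok]
        np.minimum.at(W, flat, cost_value * t)


def _cost_values(cost, grid: ChartGrid) -> np.ndarray:
    if cost is None:
        return np.ones(grid.shape)
    if hasattr(cost, "field"):  # CostField
        cost = cost.field
    if isinstance(cost, ScalarField3D):
        if cost.grid.shape != grid.shape:
            raise ValueError("cost grid does not match solver grid")
        return np.asarray(cost.values, dtype=float)
    arr = np.asarray(cost, dtype=float)
    if arr.shape != grid.shape:
        raise ValueError("cost array does not match grid shape")
    return arr


def level_set(W: ScalarField3D, T: float):
    """Triangulated T-isosurface of the distance map (the numerical SR sphere).

    Returns (verts, faces) with vertices in chart coordinates (x, y, theta),
    y/theta in [0, 2 pi).  Warns via ValueError if T is below one grid
    spacing (the surface would collapse into the seed cell).
    """
    from skimage import measure

    g = W.grid
    finite = np.isfinite(W.values)
    if not (0.0 < T < W.values[finite].max()):
        raise ValueError("T outside the range of finite W values")
    if T < g.min_spacing():
        raise ValueError("T below one grid spacing: empty/degenerate surface")
    vol = np.where(finite, W.values, 10.0 * T)
    verts, faces, _, _ = measure.marching_cubes(
        vol, level=T, spacing=(g.hx, g.hy, g.ht)
    )
    verts[:, 0] -= g.x_cap
    return verts, faces
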