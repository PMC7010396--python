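"""Grids and scalar fields over the (x, y, theta) chart of SO(3).

The latitude axis x spans [-x_cap, x_cap] (non-periodic; the chart is
singular at |x| = pi/2).  The longitude y and orientation theta axes are
periodic with period 2 pi; their nodes are k*h for k = 0..N-1 (coordinates
understood modulo 2 pi, so the identity element sits exactly on node
(center, 0, 0)).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .so3core import X_CAP_DEFAULT, wrap_angle

__all__ = ["ChartGrid", "ScalarField3D"]


@dataclass(frozen=True)
class ChartGrid:
    """Uniform chart grid with periodic y and theta axes."""

    nx: int = 51
    ny: int = 101
    nt: int = 101
    x_cap: float = X_CAP_DEFAULT

    def __post_init__(self):
        if min(self.nx, self.ny, self.nt) < 5:
            raise ValueError("grid axes need at least 5 nodes")
        if not (0.0 < self.x_cap < np.pi / 2):
            raise ValueError("x_cap must lie in (0, pi/2)")

    @property
    def hx(self) -> float:
        return 2.0 * self.x_cap / (self.nx - 1)

    @property
    def hy(self) -> float:
        return 2.0 * np.pi / self.ny

    @property
    def ht(self) -> float:
        return 2.0 * np.pi / self.nt

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.nx, self.ny, self.nt)

    @property
    def x_nodes(self) -> np.ndarray:
        return np.linspace(-self.x_cap, self.x_cap, self.nx)

    @property
    def y_nodes(self) -> np.ndarray:
        """Longitude nodes wrapped to (-pi, pi] (node 0 is y = 0)."""
        return wrap_angle(np.arange(self.ny) * self.hy)

    @property
    def theta_nodes(self) -> np.ndarray:
        return wrap_angle(np.arange(self.nt) * self.ht)

    def min_spacing(self) -> float:
        return min(self.hx, self.hy, self.ht)

    # -- continuous <-> index coordinates --------------------------------
    def to_index(self, x, y, theta):
        """Fractional array indices of chart point(s); y/theta wrap freely."""
        ix = (np.asarray(x, float) + self.x_cap) / self.hx
        iy = np.mod(np.asarray(y, float), 2.0 * np.pi) / self.hy
        it = np.mod(np.asarray(theta, float), 2.0 * np.pi) / self.ht
        return ix, iy, it

    def nearest_node(self, x, y, theta) -> tuple[int, int, int]:
        ix, iy, it = self.to_index(x, y, theta)
        return (
            int(np.clip(round(float(ix)), 0, self.nx - 1)),
            int(round(float(iy))) % self.ny,
            int(round(float(it))) % self.nt,
        )

    def node_coords(self, ix: int, iy: int, it: int) -> tuple[float, float, float]:
        return (
            -self.x_cap + ix * self.hx,
            wrap_angle(iy * self.hy),
            wrap_angle(it * self.ht),
        )

    def contains(self, x, y=None, theta=None) -> bool:
        return bool(abs(float(x)) <= self.x_cap + 1e-12)


@dataclass
class ScalarField3D:
    """Grid function over the chart (distance map W or lifted cost C)."""

    values: np.ndarray
    grid: ChartGrid
    interp_order: int = 3
    seed: tuple[float, float, float] | None = None
    _spline_coeffs: np.ndarray | None = field(default=None, repr=False)

    X_PAD = 10  # edge-replication layers so one spline mode serves all axes

    def __post_init__(self):
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"field shape {self.values.shape} != grid shape {self.grid.shape}"
            )

    def finite_max(self) -> float:
        v = self.values[np.isfinite(self.values)]
        return float(v.max()) if len(v) else np.nan

    def _coeffs(self) -> np.ndarray:
        from scipy import ndimage

        if self._spline_coeffs is None:
            v = self.values
            finite = np.isfinite(v)
            if not finite.all():
                cap = 1.5 * v[finite].max() if finite.any() else 0.0
                v = np.where(finite, v, cap)
            vp = np.concatenate(
                [np.repeat(v[:1], self.X_PAD, axis=0), v,
                 np.repeat(v[-1:], self.X_PAD, axis=0)], axis=0
            )
            if self.interp_order >= 2:
                vp = ndimage.spline_filter(vp, order=self.interp_order, mode="grid-wrap")
            self._spline_coeffs = vp
        return self._spline_coeffs

    def interpolate(self, x, y, theta):
        """Order-3 spline interpolation; y/theta periodic, x edge-clamped."""
        from scipy import ndimage

        ix, iy, it = self.grid.to_index(x, y, theta)
        scalar = np.ndim(ix) == 0 and np.ndim(iy) == 0 and np.ndim(it) == 0
        ix = np.atleast_1d(np.clip(ix, 0.0, self.grid.nx - 1.0) + self.X_PAD)
        coords = np.broadcast_arrays(ix, np.atleast_1d(iy), np.atleast_1d(it))
        out = ndimage.map_coordinates(
            self._coeffs(), coords,
            order=self.interp_order, mode="grid-wrap", prefilter=False,
        )
        return float(out[0]) if scalar else out

    def gradient_at(self, x, y, theta, rel_step: float = 0.5):
        """Chart gradient (dW/dx, dW/dy, dW/dtheta) by central differences of
        the interpolant with steps ``rel_step`` times the grid spacings."""
        g = self.grid
        dx, dy, dt = rel_step * g.hx, rel_step * g.hy, rel_step * g.ht
        return np.array(
            [
                (self.interpolate(x + dx, y, theta) - self.interpolate(x - dx, y, theta)) / (2 * dx),
                (self.interpolate(x, y + dy, theta) - self.interpolate(x, y - dy, theta)) / (2 * dy),
                (self.interpolate(x, y, theta + dt) - self.interpolate(x, y, theta - dt)) / (2 * dt),
            ]
        )
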