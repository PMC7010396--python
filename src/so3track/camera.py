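"""Schematic (reduced) eye model: central projection between spherical
object coordinates on the retina and flat camera coordinates.

All lengths are in units of the eyeball radius (R = 1).  ``a`` is the
distance from the nodal point to the eyeball center, ``c`` the distance
from the eyeball to the camera plane, and ``eta`` an overall magnification.
With the clinical defaults a = 13/21, c = 4/5 the fundus camera half-angle
psi = pi/8 images the retinal cap |y| <~ 0.63 rad.

The projection and its closed-form inverse are

    X = eta (a+c) sin x / (a + cos x cos y)
    Y = eta (a+c) cos x sin y / (a + cos x cos y)

    x = arcsin(X pbar(X, Y)),  y = arg(p1(X, Y) + i Y pbar(X, Y))

with pbar, p1 built from Xi(X,Y) = sqrt((X^2+Y^2)(1-a^2) + (a+c)^2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = ["CameraModel", "ProjectionError"]


class ProjectionError(ValueError):
    pass


@dataclass(frozen=True)
class CameraModel:
    """Schematic-eye constants (dimensionless, eyeball radius = 1)."""

    a: float = 13.0 / 21.0
    c: float = 4.0 / 5.0
    eta: float = 1.0
    psi_max: float = np.pi / 8.0

    def __post_init__(self):
        if not (0.0 <= self.a < 1.0):
            raise ValueError("nodal offset a must be in [0, 1)")
        if self.a + self.c <= 0.0 or self.eta <= 0.0:
            raise ValueError("require a + c > 0 and eta > 0")

    # -- maximal imaged object angle ------------------------------------
    def max_object_angle(self, psi: float | None = None) -> float:
        """Largest retinal angle |y| imaged at camera half-angle ``psi``.

        Solves (a + cos|y|)^2 / cos^2(psi) = (a + cos|y|)^2 + sin^2|y| for
        the unique nonnegative root of cos|y| and returns arccos of it.
        """
        psi = self.psi_max if psi is None else float(psi)
        if not (0.0 <= psi < np.pi / 2):
            raise ValueError("psi must be in [0, pi/2)")
        a = self.a
        T = np.tan(psi) ** 2
        # quadratic (T+1) u^2 + 2 a T u + (a^2 T - 1) = 0 for u = cos|y|
        disc = (a * T) ** 2 - (T + 1.0) * (a * a * T - 1.0)
        if disc < 0.0:
            raise ProjectionError("no imaged object angle for these constants")
        u = (-a * T + np.sqrt(disc)) / (T + 1.0)
        if not (-1.0 <= u <= 1.0):
            raise ProjectionError("cosine root outside [-1, 1]")
        return float(np.arccos(u))

    # -- forward / inverse central projection ---------------------------
    def project(self, x, y):
        """Flat camera coordinates (X, Y) of spherical point(s) (x, y)."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        den = self.a + np.cos(x) * np.cos(y)
        if np.any(den <= 0.0):
            raise ProjectionError("point(s) behind the nodal plane (a + cos x cos y <= 0)")
        f = (self.a + self.c) * self.eta / den
        X = f * np.sin(x)
        Y = f * np.cos(x) * np.sin(y)
        if X.ndim == 0:
            return float(X), float(Y)
        return X, Y

    def unproject(self, X, Y):
        """Spherical coordinates (x, y) of flat camera point(s) (X, Y)."""
        X = np.asarray(X, dtype=float) / self.eta
        Y = np.asarray(Y, dtype=float) / self.eta
        a, ac = self.a, self.a + self.c
        r2 = X * X + Y * Y
        xi = np.sqrt(r2 * (1.0 - a * a) + ac * ac)
        pbar = (a * ac + xi) / (r2 + ac * ac)
        p1 = (ac * xi - a * r2) / (r2 + ac * ac)
        arg = X * pbar
        if np.any(np.abs(arg) > 1.0 + 1e-12):
            raise ProjectionError("camera point outside the image of the sphere")
        x = np.arcsin(np.clip(arg, -1.0, 1.0))
        y = np.arctan2(Y * pbar, p1)
        if x.ndim == 0:
            return float(x), float(y)
        return x, y

    # -- distortion measures --------------------------------------------
    def jacobian(self, x, y):
        """Determinant J(x, y) of the sphere-to-plane map (local area change)."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        den = self.a + np.cos(x) * np.cos(y)
        if np.any(den <= 0.0):
            raise ProjectionError("singular projection point")
        J = (
            (self.a + self.c) ** 2
            * np.cos(x)
            * (1.0 + self.a * np.cos(x) * np.cos(y))
            / den**3
            * self.eta**2
        )
        return float(J) if J.ndim == 0 else J

    def global_distortion(self, y: float) -> float:
        """Relative length distortion GD(y) = |y - Y(0, y)| / |y| along x = 0.

        The removable singularity at y = 0 is filled with the analytic limit
        |1 - (a+c) eta / (a+1)|.
        """
        y = float(y)
        if y == 0.0:
            return abs(1.0 - (self.a + self.c) * self.eta / (self.a + 1.0))
        _, Y = self.project(0.0, y)
        return abs(y - Y) / abs(y)

    # -- image resampling ------------------------------------------------
    def resample_flat_to_sphere(
        self,
        image: np.ndarray,
        flat_extent: tuple[float, float],
        x_nodes: np.ndarray,
        y_nodes: np.ndarray,
        order: int = 1,
        cval: float = 0.0,
    ) -> np.ndarray:
        """Resample a flat camera image onto a spherical (x, y) chart grid.

        ``flat_extent = (X_half, Y_half)`` gives the physical half-width of the
        image: pixel (row, col) covers X in [-X_half, X_half] (columns) and
        Y in [-Y_half, Y_half] (rows).  Returns an array of shape
        ``(len(x_nodes), len(y_nodes))``.
        """
        xg, yg = np.meshgrid(x_nodes, y_nodes, indexing="ij")
        X, Y = self.project(xg, yg)
        rows, cols = _phys_to_pixel(X, Y, image.shape, flat_extent)
        return ndimage.map_coordinates(
            np.asarray(image, dtype=float), [rows, cols], order=order,
            mode="constant", cval=cval,
        )

    def resample_sphere_to_flat(
        self,
        sphere_image: np.ndarray,
        x_nodes: np.ndarray,
        y_nodes: np.ndarray,
        out_shape: tuple[int, int],
        flat_extent: tuple[float, float],
        order: int = 1,
        cval: float = 0.0,
    ) -> np.ndarray:
        """Resample a spherical-chart image to a flat camera raster."""
        X, Y = _pixel_grid(out_shape, flat_extent)
        x, y = self.unproject(X, Y)
        ix = np.interp(x, x_nodes, np.arange(len(x_nodes)))
        iy = np.interp(y, y_nodes, np.arange(len(y_nodes)))
        return ndimage.map_coordinates(
            np.asarray(sphere_image, dtype=float), [ix, iy], order=order,
            mode="constant", cval=cval,
        )


def _phys_to_pixel(X, Y, shape, extent):
    """(X, Y) physical camera coordinates -> fractional (row, col)."""
    nrow, ncol = shape
    Xh, Yh = extent
    col = (X + Xh) / (2.0 * Xh) * (ncol - 1)
    row = (Y + Yh) / (2.0 * Yh) * (nrow - 1)
    return row, col


def _pixel_grid(shape, extent):
    nrow, ncol = shape
    Xh, Yh = extent
    Y = np.linspace(-Yh, Yh, nrow)[:, None] * np.ones((1, ncol))
    X = np.ones((nrow, 1)) * np.linspace(-Xh, Xh, ncol)[None, :]
    return X, Y
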