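"""Synthetic spherical vessel phantoms and geodesic fixtures.

The phantom emulates the geometry of fundus photography: dark tubular
vessels with smooth (Gaussian) cross-section drawn on the unit sphere
within the retinal field of view (|x|, |y| <= 0.63 rad), imaged through
the schematic eye onto a flat camera raster, with optional additive
Gaussian noise.  Ground-truth centerlines are returned in chart
coordinates so trackers can be scored against them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .camera import CameraModel
from .vesselness import Image2D

__all__ = [
    "VesselPhantomSpec",
    "make_phantom",
    "make_geodesic_fixture",
    "s_tube_centerline",
]

FOV = 0.63  # retinal field of view half-angle, radians


@dataclass
class VesselPhantomSpec:
    """Specification of a spherical vessel phantom.

    centerlines: list of (n, 2) arrays of (x, y) chart samples;
    tube_width: angular half-width of a vessel (radians; Gaussian sigma);
    contrast: centerline intensity drop in [0, 1] (background is 1.0);
    noise_sigma: additive Gaussian noise level; image_size: pixels per side;
    seed_rng: RNG seed (all randomness flows through it).
    """

    centerlines: list = field(default_factory=list)
    tube_width: float = 0.012
    contrast: float = 0.7
    noise_sigma: float = 0.02
    image_size: int = 256
    seed_rng: int = 0

    def __post_init__(self):
        for c in self.centerlines:
            c = np.asarray(c, float)
            if np.any(np.abs(c) > FOV + 1e-9):
                raise ValueError("centerlines must stay within |x|,|y| <= 0.63")
        if not (0.0 <= self.contrast <= 1.0):
            raise ValueError("contrast must be in [0, 1]")


def _sphere_points(xy):
    x, y = xy[:, 0], xy[:, 1]
    cx = np.cos(x)
    return np.column_stack([cx * np.cos(y), cx * np.sin(y), np.sin(x)])


def _supersample(xy, factor=4):
    """Refine a polyline by `factor` via linear interpolation in the chart."""
    xy = np.asarray(xy, float)
    if len(xy) < 2:
        return xy
    t = np.arange(len(xy), dtype=float)
    tf = np.linspace(0.0, len(xy) - 1.0, (len(xy) - 1) * factor + 1)
    return np.column_stack([np.interp(tf, t, xy[:, 0]), np.interp(tf, t, xy[:, 1])])


def make_phantom(spec: VesselPhantomSpec, cam: CameraModel | None = None):
    """Render the phantom.

    Returns ``(image, centerlines)`` where ``image`` is a flat
    :class:`Image2D` whose extent covers the retinal field of view, and
    ``centerlines`` is the list of (supersampled) ground-truth chart
    polylines actually drawn.
    """
    cam = cam or CameraModel()
    n = spec.image_size
    # flat extent covering the (projected) field of view with a small margin
    corner = max(
        abs(v)
        for v in (
            cam.project(FOV, FOV) + cam.project(FOV, -FOV) + cam.project(0.0, FOV)
        )
    )
    Xh = Yh = 1.05 * corner
    X = np.linspace(-Xh, Xh, n)[None, :] * np.ones((n, 1))
    Y = np.linspace(-Yh, Yh, n)[:, None] * np.ones((1, n))
    x, y = cam.unproject(X.ravel(), Y.ravel())
    pix_n = _sphere_points(np.column_stack([x, y]))

    img = np.ones(n * n)
    truth = []
    # supersample centerlines so the polyline is denser than the pixel pitch
    pixel_angle = 2.0 * FOV / n
    for cl in spec.centerlines:
        cl = np.asarray(cl, float)
        seg = np.abs(np.diff(cl, axis=0)).sum(axis=1).max() if len(cl) > 1 else 0.0
        factor = max(4, int(np.ceil(4.0 * seg / pixel_angle)))
        cls = _supersample(cl, factor)
        truth.append(cls)
        m = _sphere_points(cls)
        # spherical distance from every pixel to the centerline polyline
        dmin = np.full(n * n, np.inf)
        chunk = 65536
        for lo in range(0, n * n, chunk):
            dots = pix_n[lo : lo + chunk] @ m.T
            np.minimum(
                dmin[lo : lo + chunk],
                np.arccos(np.clip(dots.max(axis=1), -1.0, 1.0)),
                out=dmin[lo : lo + chunk],
            )
        img = np.minimum(
            img, 1.0 - spec.contrast * np.exp(-(dmin**2) / (2.0 * spec.tube_width**2))
        )
    img = img.reshape(n, n)
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed_rng)
        img = img + rng.normal(0.0, spec.noise_sigma, img.shape)
    return Image2D(pixels=img, extent=(Xh, Yh)), truth


def make_geodesic_fixture(xi, h2_0, h3_0, s_end, n):
    """High-precision table of a cuspless geodesic for regression tests.

    Columns: s, x, y, theta, h1, h2, h3 (12 significant digits when saved).
    """
    from .geodesics import ModelParams, cusp_arclength_smax, cuspless_path_s

    params = ModelParams(xi)
    if abs(h2_0) > 1e-12 or abs(h3_0) > 1e-12:
        smax = cusp_arclength_smax(h2_0, h3_0, params)
        if s_end > smax + 1e-12:
            raise ValueError(f"s_end past the first cusp (s_max = {smax:.6g})")
    path = cuspless_path_s(h2_0, h3_0, params, s_end, n - 1)
    return np.column_stack([path.param_values, path.states, path.momenta])


def s_tube_centerline(
    amplitude: float = 0.17,
    y_half: float = 0.45,
    n: int = 121,
) -> np.ndarray:
    """S-shaped test vessel: x = A sin(pi * y / y_half), y in [-y_half, y_half]."""
    y = np.linspace(-y_half, y_half, n)
    x = amplitude * np.sin(np.pi * y / y_half)
    return np.column_stack([x, y])
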