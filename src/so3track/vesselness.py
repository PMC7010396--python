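"""Multiscale Hessian vesselness and the external cost on the SO(3) chart.

A fundus-style image shows vessels as dark tubes on a bright background.
The per-scale response at Gaussian scale ``s = sigma^2/2`` is

    V_s = exp(-lam1^2 / (2 beta^2 lam2^2))
          * (1 - exp(-(lam1^2 + lam2^2) / (2 c^2))) * U(lam2),

with (lam1, lam2) the Gaussian-Hessian eigenvalues ordered by
|lam1| <= |lam2| and U the unit step (lam2 >= 0 selects intensity valleys,
i.e. dark-on-bright tubes).  VF is the maximum over scales.  The cost on
the sphere is

    G(x, y) = (1 + VF(Pi(x, y)) / (lambda ||VF||_inf^2))^(-1),

lifted to SO(3) by replication along theta (cost depends on the spherical
coordinates only).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .camera import CameraModel
from .grid import ChartGrid, ScalarField3D

__all__ = [
    "Image2D",
    "VesselnessParams",
    "CostField",
    "hessian_eigenvalues",
    "vesselness",
    "external_cost",
    "load_image",
]


@dataclass
class Image2D:
    """Flat camera image.

    ``pixels[row, col]``: row 0 at Y = -extent[1] (Y increases downward by
    convention here), column 0 at X = -extent[0].  ``extent = (Xh, Yh)``
    are physical half-widths in camera units.
    """

    pixels: np.ndarray
    extent: tuple[float, float]

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2 or min(self.pixels.shape) < 16:
            raise ValueError("image must be 2D, at least 16x16 pixels")
        if not np.isfinite(self.pixels).all():
            raise ValueError("image has non-finite pixels")

    @property
    def shape(self):
        return self.pixels.shape

    def pixel_index(self, X, Y):
        """Fractional (row, col) of physical camera coordinates."""
        nrow, ncol = self.pixels.shape
        Xh, Yh = self.extent
        col = (np.asarray(X, float) + Xh) / (2 * Xh) * (ncol - 1)
        row = (np.asarray(Y, float) + Yh) / (2 * Yh) * (nrow - 1)
        return row, col


@dataclass(frozen=True)
class VesselnessParams:
    """Parameters of the multiscale vesselness filter and the cost map.

    beta: plate/line discriminator; c_resp: structureness constant;
    scales: Gaussian scales s = sigma^2/2 in pixel units; lam: cost
    strength lambda (large lam -> cost-dominant tracking).
    """

    beta: float = 0.3
    c_resp: float = 0.3
    scales: tuple = (2.0, 3.0, 4.0, 5.0)
    lam: float = 50.0
    normalize_vesselness: bool = False
    delta_floor: float = 1e-3

    def __post_init__(self):
        if self.beta <= 0 or self.c_resp <= 0 or self.lam <= 0:
            raise ValueError("beta, c_resp, lam must be positive")
        if len(self.scales) == 0 or min(self.scales) <= 0:
            raise ValueError("scales must be nonempty and positive")


@dataclass
class CostField:
    """External cost lifted to the chart: values in (0, 1], >= delta_floor,
    constant along theta."""

    field: ScalarField3D
    delta_floor: float


def hessian_eigenvalues(image, scale: float):
    """Gaussian-Hessian eigenvalues at scale s = sigma^2/2, ordered |l1|<=|l2|.

    Derivatives are Gaussian (sigma = sqrt(2 s), truncated at 4 sigma,
    reflective boundary).  Returns (lam1, lam2) as 2D arrays.
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    pix = image.pixels if isinstance(image, Image2D) else np.asarray(image, float)
    # remove the mean: the truncated derivative kernels do not sum exactly
    # to zero, so this makes the response exactly offset-invariant
    pix = pix - pix.mean()
    sigma = np.sqrt(2.0 * scale)
    opts = dict(sigma=sigma, mode="reflect", truncate=4.0)
    Hrr = ndimage.gaussian_filter(pix, order=(2, 0), **opts)
    Hcc = ndimage.gaussian_filter(pix, order=(0, 2), **opts)
    Hrc = ndimage.gaussian_filter(pix, order=(1, 1), **opts)
    tr = Hrr + Hcc
    disc = np.sqrt((Hrr - Hcc) ** 2 + 4.0 * Hrc**2)
    la = 0.5 * (tr + disc)
    lb = 0.5 * (tr - disc)
    swap = np.abs(la) > np.abs(lb)
    lam1 = np.where(swap, lb, la)
    lam2 = np.where(swap, la, lb)
    return lam1, lam2


def vesselness(image, p: VesselnessParams) -> np.ndarray:
    """Multiscale vesselness VF: per-scale response maximized over scales."""
    pix = image.pixels if isinstance(image, Image2D) else np.asarray(image, float)
    out = np.zeros_like(pix, dtype=float)
    for s in p.scales:
        lam1, lam2 = hessian_eigenvalues(pix, s)
        with np.errstate(divide="ignore", invalid="ignore"):
            aniso = np.exp(-(lam1**2) / (2.0 * p.beta**2 * lam2**2))
        aniso = np.where(lam2 == 0.0, 0.0, aniso)
        strength = 1.0 - np.exp(-(lam1**2 + lam2**2) / (2.0 * p.c_resp**2))
        resp = aniso * strength * (lam2 >= 0.0)
        out = np.maximum(out, resp)
    return out


def external_cost(
    VF: np.ndarray,
    image: Image2D,
    cam: CameraModel,
    p: VesselnessParams,
    grid: ChartGrid,
    rotation: np.ndarray | None = None,
) -> CostField:
    """Lift the vesselness response to a cost field on the chart grid.

    Each chart node (x, y) is projected to the flat image through the
    schematic eye and VF is sampled bilinearly; out-of-image nodes get
    cost 1.  ``rotation`` optionally pre-rotates the sphere point (used to
    shift the tracking seed to the identity).  The cost is replicated
    along theta and floored at ``delta_floor``.
    """
    vmax = float(np.max(np.abs(VF)))
    if vmax == 0.0:
        values = np.ones(grid.shape)
        return CostField(ScalarField3D(values, grid, interp_order=1), p.delta_floor)
    VFs = VF / vmax if p.normalize_vesselness else VF
    denom_norm = float(np.max(np.abs(VFs)))

    xg, yg = np.meshgrid(grid.x_nodes, grid.y_nodes, indexing="ij")
    if rotation is not None:
        cx = np.cos(xg)
        n = np.stack([cx * np.cos(yg), cx * np.sin(yg), np.sin(xg)])
        nr = np.einsum("ab,bij->aij", rotation, n)
        xg = np.arcsin(np.clip(nr[2], -1.0, 1.0))
        yg = np.arctan2(nr[1], nr[0])

    den = cam.a + np.cos(xg) * np.cos(yg)
    visible = den > 1e-9
    X = np.where(visible, (cam.a + cam.c) * np.sin(xg) * cam.eta / np.where(visible, den, 1.0), 0.0)
    Y = np.where(visible, (cam.a + cam.c) * np.cos(xg) * np.sin(yg) * cam.eta / np.where(visible, den, 1.0), 0.0)
    row, col = image.pixel_index(X, Y)
    nrow, ncol = image.shape
    inside = visible & (row >= 0) & (row <= nrow - 1) & (col >= 0) & (col <= ncol - 1)
    vf_xy = ndimage.map_coordinates(
        np.asarray(VFs, float), [row, col], order=1, mode="constant", cval=0.0
    )
    vf_xy = np.where(inside, vf_xy, 0.0)

    g_xy = 1.0 / (1.0 + vf_xy / (p.lam * denom_norm**2))
    g_xy = np.maximum(g_xy, p.delta_floor)
    values = np.repeat(g_xy[:, :, None], grid.nt, axis=2)
    return CostField(ScalarField3D(values, grid, interp_order=1), p.delta_floor)


def load_image(path, channel: str = "green") -> np.ndarray:
    """Read a grayscale raster; color inputs use the fundus green-channel
    convention (override with channel='luminance')."""
    import imageio.v3 as iio

    arr = np.asarray(iio.imread(path), dtype=float)
    if arr.ndim == 3:
        if channel == "green":
            arr = arr[..., 1]
        elif channel == "luminance":
            arr = arr[..., :3] @ np.array([0.2126, 0.7152, 0.0722])
        else:
            raise ValueError("channel must be 'green' or 'luminance'")
    if arr.max() > 1.0:
        arr = arr / (255.0 if arr.max() < 256 else 65535.0)
    return arr
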