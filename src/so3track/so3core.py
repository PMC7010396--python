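"""Parameterization of SO(3) used throughout the tracker.

A rotation is charted by three angles ``(x, y, theta)`` via

    R(x, y, theta) = exp(y A3) exp(-x A2) exp(theta A1),

where ``A1, A2, A3`` are the skew generators of rotations about the
coordinate axes.  The pair ``(x, y)`` are latitude/longitude on the image
sphere (the first column of ``R`` is the sphere point), and ``theta`` is the
orientation of the tracked curve.  The chart is singular at the poles
``|x| = pi/2``; retinal data lives well inside ``|x| <= 0.63``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "GroupPoint",
    "ChartSingularityError",
    "wrap_angle",
    "rotation_matrix",
    "chart_from_matrix",
    "spherical_projection",
    "frame",
    "coframe",
    "A1",
    "A2",
    "A3",
    "X_CAP_DEFAULT",
]

#: generators of so(3): A_i is the skew matrix of rotation about axis e_i,
#: i.e. A_i v = e_i x v.
A1 = np.array([[0.0, 0.0, 0.0], [0.0, 0.0, -1.0], [0.0, 1.0, 0.0]])
A2 = np.array([[0.0, 0.0, 1.0], [0.0, 0.0, 0.0], [-1.0, 0.0, 0.0]])
A3 = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 0.0]])

#: default working half-range for the latitude axis of grids (radians).
X_CAP_DEFAULT = 1.4

_POLE_MARGIN = 1e-6


class ChartSingularityError(ValueError):
    """Raised when an operation needs sec(x)/tan(x) at |x| ~ pi/2."""


def wrap_angle(a):
    """Wrap angle(s) to the principal branch (-pi, pi]."""
    a = np.asarray(a, dtype=float)
    w = np.mod(-a + np.pi, 2.0 * np.pi)
    out = -(w - np.pi)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class GroupPoint:
    """Chart coordinates (x, y, theta) of a rotation.

    ``x`` is the latitude in [-pi/2, pi/2]; ``y`` and ``theta`` are stored
    wrapped to (-pi, pi].  The identity element is ``(0, 0, 0)``.
    """

    x: float
    y: float
    theta: float

    def __post_init__(self):
        if not np.isfinite([self.x, self.y, self.theta]).all():
            raise ValueError("non-finite chart coordinates")
        if abs(self.x) > np.pi / 2 + 1e-12:
            raise ValueError(f"latitude |x|={abs(self.x):.6f} exceeds pi/2")
        object.__setattr__(self, "x", float(np.clip(self.x, -np.pi / 2, np.pi / 2)))
        object.__setattr__(self, "y", wrap_angle(self.y))
        object.__setattr__(self, "theta", wrap_angle(self.theta))

    @classmethod
    def identity(cls) -> "GroupPoint":
        return cls(0.0, 0.0, 0.0)

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y, self.theta])


def rotation_matrix(g: GroupPoint | tuple) -> np.ndarray:
    """3x3 rotation matrix of the chart point ``g``.

    Equals ``exp(y A3) exp(-x A2) exp(theta A1)`` written out in closed form.
    """
    x, y, th = _coords(g)
    cx, sx = np.cos(x), np.sin(x)
    cy, sy = np.cos(y), np.sin(y)
    ct, st = np.cos(th), np.sin(th)
    # exp(y A3) @ exp(-x A2) @ exp(th A1)
    return np.array(
        [
            [cx * cy, -cy * sx * st - sy * ct, -cy * sx * ct + sy * st],
            [cx * sy, -sy * sx * st + cy * ct, -sy * sx * ct - cy * st],
            [sx, cx * st, cx * ct],
        ]
    )


def chart_from_matrix(R: np.ndarray) -> GroupPoint:
    """Extract chart coordinates from a rotation matrix.

    Uses principal-branch ``arg`` throughout:
    ``x = arg(sqrt(R11^2 + R21^2) + i R31)``, ``y = arg(R11 + i R21)``,
    ``theta = arg(R33 + i R32)``.  Well defined away from the poles
    ``|x| = pi/2`` (where y and theta are not separately determined).
    """
    R = np.asarray(R, dtype=float)
    cxa = np.hypot(R[0, 0], R[1, 0])
    x = np.arctan2(R[2, 0], cxa)
    if cxa < 1e-12:
        raise ChartSingularityError("chart extraction at a pole |x|=pi/2")
    y = np.arctan2(R[1, 0], R[0, 0])
    th = np.arctan2(R[2, 1], R[2, 2])
    return GroupPoint(x, y, th)


def spherical_projection(g: GroupPoint | tuple) -> np.ndarray:
    """Project the rotation to the sphere: R e1 = (cos x cos y, cos x sin y, sin x)."""
    x, y, _ = _coords(g)
    cx = np.cos(x)
    return np.array([cx * np.cos(y), cx * np.sin(y), np.sin(x)])


def frame(g: GroupPoint | tuple) -> np.ndarray:
    """Left-invariant frame X1, X2, X3 at ``g``: rows of coefficients
    w.r.t. (d/dx, d/dy, d/dtheta).

        X1 = cos(th) dx - sec(x) sin(th) dy + tan(x) sin(th) dth
        X2 = dth
        X3 = sin(th) dx + sec(x) cos(th) dy - tan(x) cos(th) dth
    """
    x, _, th = _coords(g)
    if abs(x) >= np.pi / 2 - _POLE_MARGIN:
        raise ChartSingularityError(f"frame undefined at |x|={abs(x):.6f} (pole)")
    sec, tan = 1.0 / np.cos(x), np.tan(x)
    ct, st = np.cos(th), np.sin(th)
    return np.array(
        [
            [ct, -sec * st, tan * st],
            [0.0, 0.0, 1.0],
            [st, sec * ct, -tan * ct],
        ]
    )


def coframe(g: GroupPoint | tuple) -> np.ndarray:
    """Dual coframe omega^1, omega^2, omega^3 at ``g``: rows of coefficients
    w.r.t. (dx, dy, dtheta).

        omega^1 = cos(th) dx - cos(x) sin(th) dy
        omega^2 = sin(x) dy + dth
        omega^3 = sin(th) dx + cos(x) cos(th) dy
    """
    x, _, th = _coords(g)
    cx, sx = np.cos(x), np.sin(x)
    ct, st = np.cos(th), np.sin(th)
    return np.array(
        [
            [ct, -cx * st, 0.0],
            [0.0, sx, 1.0],
            [st, cx * ct, 0.0],
        ]
    )


def orientation_from_tangent(x: float, dx: float, dy: float) -> float:
    """Orientation angle theta whose spatial motion direction matches the
    chart tangent (dx, dy) at latitude x.

    The spatial generator moves as (dx/ds, dy/ds) = (cos th, -sec x sin th),
    so theta = atan2(-cos(x) dy, dx).
    """
    return float(np.arctan2(-np.cos(x) * dy, dx))


def _coords(g):
    if isinstance(g, GroupPoint):
        return g.x, g.y, g.theta
    x, y, th = (float(v) for v in g)
    return x, y, th
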