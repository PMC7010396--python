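"""Run configuration: every tunable of the pipeline with its defaults."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np

from .camera import CameraModel
from .so3core import X_CAP_DEFAULT

__all__ = ["RunConfig", "PRESETS"]


@dataclass
class RunConfig:
    """All pipeline tunables, serializable to/from YAML.

    Geometry: xi (stiffness), eps (anisotropy of the Riemannian
    approximation).  Cost: lam (cost strength), beta/c_resp/scales
    (vesselness).  Camera: a, c, eta.  Grid: nx/ny/nt nodes, x_cap.
    """

    xi: float = 1.0
    eps: float = 0.1
    lam: float = 50.0
    beta: float = 0.3
    c_resp: float = 0.3
    scales: tuple = (2.0, 3.0, 4.0, 5.0)
    normalize_vesselness: bool = False
    cam_a: float = 13.0 / 21.0
    cam_c: float = 4.0 / 5.0
    eta: float = 1.0
    grid_nx: int = 51
    grid_ny: int = 101
    grid_nt: int = 101
    x_cap: float = X_CAP_DEFAULT
    scheme: str = "anisotropic_fast_marching"
    seed_rng: int = 0

    def camera_model(self) -> CameraModel:
        return CameraModel(a=self.cam_a, c=self.cam_c, eta=self.eta)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["scales"] = list(self.scales)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "scales" in d:
            d["scales"] = tuple(float(s) for s in d["scales"])
        return cls(**d)

    def to_yaml(self, path):
        import yaml

        with open(path, "w") as f:
            yaml.safe_dump(self.to_dict(), f, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as f:
            return cls.from_dict(yaml.safe_load(f))


#: named presets: the reference-resolution uniform-cost verification run and
#: the curvature-comparison setting (xi=3, lambda=50, eta=2).
PRESETS = {
    "uniform-cost-verification": RunConfig(
        xi=1.5, grid_nx=51, grid_ny=101, grid_nt=101, x_cap=1.5
    ),
    "reference-resolution": RunConfig(
        xi=1.5, grid_nx=201, grid_ny=401, grid_nt=401, x_cap=1.5
    ),
    "curvature-comparison": RunConfig(xi=3.0, lam=50.0, eta=2.0),
}
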