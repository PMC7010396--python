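import numpy as np
import pytest

from so3track import ChartGrid, SolverParams, solve_eikonal


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def coarse_grid():
    """Small chart grid shared by the eikonal/tracking unit tests."""
    return ChartGrid(nx=21, ny=41, nt=41, x_cap=1.4)


@pytest.fixture(scope="session")
def W_uniform_xi1(coarse_grid):
    """Uniform-cost distance map at xi = 1 on the coarse grid."""
    return solve_eikonal(None, SolverParams(xi=1.0, eps=0.1), coarse_grid)


@pytest.fixture(scope="session")
def W_uniform_xi15(coarse_grid):
    """Uniform-cost distance map at xi = 1.5 on the coarse grid."""
    return solve_eikonal(None, SolverParams(xi=1.5, eps=0.1), coarse_grid)
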