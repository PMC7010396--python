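"""Exact SR geodesics: closed forms vs ODE oracles, cusps, conservation."""

import numpy as np
import pytest
from scipy.integrate import quad, solve_ivp
from scipy.optimize import brentq

from so3track.geodesics import (
    CuspError, GeodesicPath, ModelParams, Momentum, PendulumState,
    classify_case, closed_form_path_t, cusp_arclength_smax,
    cuspless_geodesic_s, cuspless_path_s, exponential_map,
    geodesic_closed_form_t, geodesic_curvature_gauss_bonnet,
    pendulum_dynamics, t_of_s, vertical_solution_s, wavefront, _full_rhs,
)

XIS = (0.5, 1.0, 1.5)


def unit_momentum(params, beta, h3):
    return Momentum.unit_speed(params, beta, h3)


# ---------------------------------------------------------------------------
# classification and pendulum form
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "xi,M,label",
    [
        (0.5, 1.0, "elliptic"),
        (1.0, 1.5, "linear"),
        (1.5, 2.0, "hyperbolic"),
        (0.5, 0.5, "equilibrium_point"),
        (1.0, 1.0, "line_segment"),
        (2.0, 2.0, "crossing_segments"),
        (0.5, 0.1, "no_solution"),
        (2.0, 0.5, "no_solution"),
    ],
)
def test_vertical_phase_portrait_classification(xi, M, label):
    assert classify_case(ModelParams(xi), M) == label


class TestPendulum:
    def test_linear_case_uniform_rotation(self):
        st = PendulumState(beta=0.7, c=1.3, r=0.0)
        bdot, cdot = pendulum_dynamics(st)
        assert (bdot, cdot) == (1.3, 0.0)

    def test_equilibrium(self):
        st = PendulumState(beta=0.0, c=0.0, r=0.5)
        assert pendulum_dynamics(st) == (0.0, 0.0)

    def test_pendulum_maps_onto_vertical_dynamics(self, rng):
        # a trajectory of (beta, c) pushed through h1 = xi cos(beta/2) etc.
        # must satisfy the momentum equations
        xi = 0.7
        params = ModelParams(xi)
        r = 1 / xi**2 - 1

        def rhs(t, z):
            return [z[1], -r * np.sin(z[0])]

        sol = solve_ivp(rhs, (0, 3), [0.9, 0.4], dense_output=True,
                        rtol=1e-11, atol=1e-11)
        for t in np.linspace(0.1, 2.9, 7):
            b, c = sol.sol(t)
            bd, cd = rhs(t, (b, c))
            h1, h2, h3 = xi * np.cos(b / 2), np.sin(b / 2), xi * c / 2
            h1d = -0.5 * xi * np.sin(b / 2) * bd
            h2d = 0.5 * np.cos(b / 2) * bd
            h3d = xi * cd / 2
            assert h1d == pytest.approx(-h2 * h3, abs=1e-8)
            assert h2d == pytest.approx(h1 * h3 / xi**2, abs=1e-8)
            assert h3d == pytest.approx((1 - 1 / xi**2) * h1 * h2, abs=1e-8)

    def test_symmetry_beta_plus_pi_flips_r(self):
        # trajectories for (beta, r) and (beta + pi, -r) coincide
        r = 0.6

        def rhs(t, z, rr):
            return [z[1], -rr * np.sin(z[0])]

        a = solve_ivp(rhs, (0, 4), [0.5, 0.3], args=(r,), rtol=1e-11,
                      atol=1e-11, t_eval=np.linspace(0, 4, 30))
        b = solve_ivp(rhs, (0, 4), [0.5 + np.pi, 0.3], args=(-r,), rtol=1e-11,
                      atol=1e-11, t_eval=np.linspace(0, 4, 30))
        assert np.abs((b.y[0] - np.pi) - a.y[0]).max() < 1e-8
        assert np.abs(b.y[1] - a.y[1]).max() < 1e-8


# ---------------------------------------------------------------------------
# exponential map (ODE route)
# ---------------------------------------------------------------------------

class TestExponentialMap:
    def test_great_circle(self):
        params = ModelParams(1.5)
        path = exponential_map(Momentum(1.5, 0.0, 0.0), params, 1.2, 30)
        assert np.abs(path.momenta - path.momenta[0]).max() < 1e-9
        assert np.allclose(path.states[:, 0], path.param_values / 1.5, atol=1e-9)
        assert np.abs(path.states[:, 1:]).max() < 1e-9

    def test_linear_case_momentum_rotation(self):
        # xi = 1: h3 constant, h1 + i h2 rotates at rate h3
        params = ModelParams(1.0)
        h0 = Momentum(np.cos(0.3), np.sin(0.3), 0.8)
        path = exponential_map(h0, params, 2.0, 40)
        t = path.param_values
        z = (h0.h1 + 1j * h0.h2) * np.exp(1j * h0.h3 * t)
        assert np.abs(path.momenta[:, 0] - z.real).max() < 1e-8
        assert np.abs(path.momenta[:, 1] - z.imag).max() < 1e-8
        assert np.abs(path.momenta[:, 2] - h0.h3).max() < 1e-10

    def test_richardson_step_halving(self):
        params = ModelParams(0.7)
        h0 = Momentum(0.7 * np.cos(0.4), np.sin(0.4), 0.3)
        a = exponential_map(h0, params, 2.0, 1, rtol=1e-10, atol=1e-10)
        b = exponential_map(h0, params, 2.0, 1, rtol=1e-13, atol=1e-13)
        assert np.abs(a.states[-1] - b.states[-1]).max() < 1e-7

    def test_conservation_of_hamiltonian_and_casimir(self, rng):
        for xi in XIS:
            params = ModelParams(xi)
            for _ in range(4):
                h0 = unit_momentum(params, rng.uniform(0, 4 * np.pi),
                                   rng.uniform(-2, 2))
                path = exponential_map(h0, params, 2.5, 25)
                H2 = path.momenta[:, 0] ** 2 / xi**2 + path.momenta[:, 1] ** 2
                M2 = (path.momenta**2).sum(axis=1)
                assert np.abs(H2 - 1.0).max() < 1e-7
                assert np.abs(M2 - M2[0]).max() < 1e-7

    def test_rejects_off_cylinder_momentum(self):
        with pytest.raises(ValueError):
            exponential_map(Momentum(1.0, 1.0, 0.0), ModelParams(1.5), 1.0)

    def test_chart_exit_flagged(self):
        # a meridian geodesic reaches the pole x = pi/2 at t = xi * pi/2
        params = ModelParams(1.0)
        path = exponential_map(Momentum(1.0, 0.0, 0.0), params, 3.0, 30)
        assert path.chart_exit
        assert np.abs(path.states[:, 0]).max() < np.pi / 2


# ---------------------------------------------------------------------------
# closed form in t vs ODE oracle
# ---------------------------------------------------------------------------

class TestClosedFormT:
    def test_starts_at_identity(self):
        params = ModelParams(0.8)
        g = geodesic_closed_form_t(unit_momentum(params, 1.0, 0.5), params, 0.0)
        assert np.allclose(g.as_array(), 0.0, atol=1e-14)

    def test_great_circle_reduction(self):
        params = ModelParams(1.5)
        g = geodesic_closed_form_t(Momentum(1.5, 0.0, 0.0), params, 0.9)
        assert g.as_array() == pytest.approx([0.6, 0.0, 0.0], abs=1e-12)

    @pytest.mark.parametrize("xi", XIS)
    def test_matches_ode_integration(self, xi, rng):
        params = ModelParams(xi)
        for _ in range(7):
            h0 = unit_momentum(params, rng.uniform(0, 4 * np.pi),
                               rng.uniform(-2, 2))
            if abs(h0.h2) < 1e-3 and abs(h0.h3) < 1e-3:
                continue
            cf = closed_form_path_t(h0, params, 3.0, 50)
            sol = solve_ivp(
                _full_rhs, (0, 3.0), [0, 0, 0, h0.h1, h0.h2, h0.h3],
                t_eval=cf.param_values, args=(xi,), method="DOP853",
                rtol=1e-12, atol=1e-12,
            )
            ode_states = sol.y[:3].T
            # compare via sin/cos to avoid 2-pi branch artifacts
            err = max(
                np.abs(np.sin(ode_states) - np.sin(cf.states)).max(),
                np.abs(np.cos(ode_states) - np.cos(cf.states)).max(),
            )
            assert err < 1e-6


# ---------------------------------------------------------------------------
# spherical-arclength forms
# ---------------------------------------------------------------------------

class TestVerticalSolutionS:
    def test_initial_value(self):
        params = ModelParams(0.5)
        m = vertical_solution_s(0.3, 0.2, params, 0.0)
        assert m.h1 == pytest.approx(0.5 * np.sqrt(1 - 0.09), rel=1e-12)
        assert (m.h2, m.h3) == (0.3, 0.2)

    def test_linear_branch(self):
        params = ModelParams(1.0)
        m = vertical_solution_s(0.2, 0.5, params, 0.8)
        assert m.h2 == pytest.approx(0.2 + 0.5 * 0.8, rel=1e-14)
        assert m.h3 == pytest.approx(0.5, rel=1e-14)

    def test_matches_ode_oracle(self):
        # vertical part in s: h2' = h3, h3' = (xi^2 - 1) h2
        params = ModelParams(0.5)
        sol = solve_ivp(
            lambda s, z: [z[1], (0.25 - 1.0) * z[0]], (0, 1.0), [0.3, 0.2],
            rtol=1e-12, atol=1e-12, t_eval=[1.0],
        )
        m = vertical_solution_s(0.3, 0.2, params, 1.0)
        assert m.h2 == pytest.approx(sol.y[0, -1], abs=1e-9)
        assert m.h3 == pytest.approx(sol.y[1, -1], abs=1e-9)

    def test_past_cusp_rejected(self):
        params = ModelParams(1.0)
        with pytest.raises(CuspError):
            vertical_solution_s(0.0, 1.0, params, 1.5)  # h2 = 1.5 > 1


class TestCuspArclength:
    def test_linear_case_unit_momentum(self):
        # xi = 1, (h2, h3)(0) = (0, 1): h2(s) = s, cusp at s = 1
        assert cusp_arclength_smax(0.0, 1.0, ModelParams(1.0)) == pytest.approx(1.0)

    def test_equatorial_geodesic_never_cusps(self):
        assert cusp_arclength_smax(0.0, 0.0, ModelParams(1.0)) == np.inf

    def test_immediate_cusp_rejected(self):
        with pytest.raises(CuspError):
            cusp_arclength_smax(1.0, 0.3, ModelParams(1.0))

    def test_closed_form_vs_bisection(self, rng):
        # 200 random (xi, h2_0, h3_0): closed form equals the first root of
        # h1(s) = 0 found by scan + bisection
        checked = 0
        for _ in range(200):
            xi = rng.uniform(0.3, 2.5)
            params = ModelParams(xi)
            h2_0 = rng.uniform(-0.99, 0.99)
            h3_0 = rng.uniform(-2.0, 2.0)
            s_cf = cusp_arclength_smax(h2_0, h3_0, params)

            def h2_of_s(s):
                if xi == 1.0:
                    return h2_0 + h3_0 * s
                chi = params.chi
                return (h2_0 * np.cosh(s * chi)
                        + (h3_0 / chi) * np.sinh(s * chi)).real

            ss = np.linspace(1e-9, 40.0, 40001)
            vals = 1.0 - np.array([h2_of_s(s) for s in ss]) ** 2
            idx = np.where(vals <= 0)[0]
            if len(idx) == 0:
                assert s_cf == np.inf or s_cf > 40.0
                continue
            i = idx[0]
            s_oracle = brentq(lambda s: 1.0 - h2_of_s(s) ** 2,
                              ss[i - 1], ss[i], xtol=1e-13)
            assert s_cf == pytest.approx(s_oracle, abs=1e-8)
            checked += 1
        assert checked > 100


class TestCusplessGeodesicS:
    def test_starts_at_identity(self):
        g = cuspless_geodesic_s(0.3, 0.1, ModelParams(0.8), 0.0)
        assert np.allclose(g.as_array(), 0.0, atol=1e-14)

    def test_meridian(self):
        g = cuspless_geodesic_s(0.0, 0.0, ModelParams(1.3), 0.7)
        assert g.as_array() == pytest.approx([0.7, 0.0, 0.0], abs=1e-12)

    def test_past_cusp_rejected(self):
        params = ModelParams(1.0)
        with pytest.raises(CuspError):
            cuspless_geodesic_s(0.0, 1.0, params, 1.5)

    def test_h1_positive_until_cusp_and_zero_at_cusp(self, rng):
        for xi in XIS:
            params = ModelParams(xi)
            for _ in range(5):
                h2_0 = rng.uniform(-0.9, 0.9)
                h3_0 = rng.uniform(-1.5, 1.5)
                smax = cusp_arclength_smax(h2_0, h3_0, params)
                if not np.isfinite(smax):
                    continue
                hs = vertical_solution_s(h2_0, h3_0, params,
                                         np.linspace(0, smax, 50))
                assert (hs[:-1, 0] > 0).all()
                assert abs(hs[-1, 0]) < 1e-7  # h1(s_max) = 0

    @pytest.mark.parametrize("xi", XIS)
    def test_matches_reparameterized_ode(self, xi, rng):
        params = ModelParams(xi)
        checked = 0
        for _ in range(6):
            h2_0 = rng.uniform(-0.9, 0.9)
            h3_0 = rng.uniform(-1.5, 1.5)
            smax = cusp_arclength_smax(h2_0, h3_0, params)
            s_end = min(0.95 * smax, np.pi / 2)
            if s_end < 0.05:
                continue
            path = cuspless_path_s(h2_0, h3_0, params, s_end, 15)

            def dtds(s):
                m = vertical_solution_s(h2_0, h3_0, params, np.atleast_1d(s))
                return xi**2 / m[0, 0]

            ts = [0.0]
            for i in range(1, len(path.param_values)):
                v, _ = quad(dtds, path.param_values[i - 1],
                            path.param_values[i], epsabs=1e-12, epsrel=1e-12)
                ts.append(ts[-1] + v)
            h10 = xi * np.sqrt(1 - h2_0**2)
            sol = solve_ivp(
                _full_rhs, (0, ts[-1]), [0, 0, 0, h10, h2_0, h3_0],
                t_eval=ts, args=(xi,), method="DOP853",
                rtol=1e-13, atol=1e-13,
            )
            err = max(
                np.abs(np.sin(sol.y[:3].T) - np.sin(path.states)).max(),
                np.abs(np.cos(sol.y[:3].T) - np.cos(path.states)).max(),
            )
            assert err < 1e-6
            checked += 1
        assert checked >= 3

    def test_elliptic_fast_path_agrees_with_quadrature(self, rng):
        checked = 0
        while checked < 4:
            xi = rng.uniform(0.3, 0.9)
            params = ModelParams(xi)
            h2_0 = rng.uniform(-0.6, 0.6)
            h3_0 = rng.uniform(-0.3, 0.3)
            M = np.sqrt(xi**2 * (1 - h2_0**2) + h2_0**2 + h3_0**2)
            if not (xi < M < 1.0):
                continue
            smax = cusp_arclength_smax(h2_0, h3_0, params)
            s_end = min(0.9 * smax, 2.0)
            a = cuspless_path_s(h2_0, h3_0, params, s_end, 20,
                                use_elliptic_fast_path=True)
            b = cuspless_path_s(h2_0, h3_0, params, s_end, 20,
                                use_elliptic_fast_path=False)
            assert np.abs(a.states - b.states).max() < 1e-10
            checked += 1

    def test_projected_curve_is_unit_speed(self, rng):
        params = ModelParams(1.5)
        path = cuspless_path_s(0.4, 0.2, params, 0.8, 200)
        n = path.sphere_curve()
        ds = path.param_values[1] - path.param_values[0]
        speed = np.linalg.norm(np.diff(n, axis=0), axis=1) / ds
        assert np.abs(speed - 1.0).max() < 1e-4


# ---------------------------------------------------------------------------
# reparameterization and curvature
# ---------------------------------------------------------------------------

class TestTOfS:
    def test_meridian_uniform_cost(self):
        params = ModelParams(1.3)
        path = cuspless_path_s(0.0, 0.0, params, 1.0, 50)
        ts = t_of_s(path)
        assert np.allclose(ts, 1.3 * path.param_values, atol=1e-12)

    def test_cost_linearity(self):
        params = ModelParams(0.8)
        path = cuspless_path_s(0.3, 0.1, params, 0.6, 50)
        t1 = t_of_s(path)
        t2 = t_of_s(path, cost_values=2.0 * np.ones(len(path.param_values)))
        assert np.allclose(t2, 2.0 * t1, rtol=1e-12)

    def test_two_route_consistency(self):
        # integrand c*sqrt(xi^2 + kg^2) equals xi^2/h1 pointwise
        params = ModelParams(1.5)
        path = cuspless_path_s(0.4, -0.3, params, 0.7, 100)
        h1, h2 = path.momenta[:, 0], path.momenta[:, 1]
        kg = params.xi**2 * h2 / h1
        lhs = np.sqrt(params.xi**2 + kg**2)
        rhs = params.xi**2 / h1
        assert np.abs(lhs - rhs).max() < 1e-6


class TestGaussBonnetCurvature:
    def test_great_circle_is_flat(self):
        s = np.linspace(0, 1.5, 100)
        n = np.column_stack([np.cos(s), np.sin(s), np.zeros_like(s)])
        kg = geodesic_curvature_gauss_bonnet(n, s)
        assert np.abs(kg).max() < 1e-4

    def test_latitude_circle(self):
        # small circle at latitude x0 has constant k_g = tan(x0)
        x0 = 0.5
        r = np.cos(x0)
        s = np.linspace(0, 2.0, 300)
        phi = s / r
        n = np.column_stack([r * np.cos(phi), r * np.sin(phi),
                             np.full_like(phi, np.sin(x0))])
        kg = geodesic_curvature_gauss_bonnet(n, s)
        assert np.abs(np.abs(kg[5:-5]) - np.tan(x0)).max() / np.tan(x0) < 1e-3

    def test_matches_momentum_ratio_along_geodesic(self):
        params = ModelParams(1.5)
        path = cuspless_path_s(0.4, 0.2, params, 0.8, 400)
        kg_fd = geodesic_curvature_gauss_bonnet(
            path.sphere_curve(), path.param_values
        )
        kg_mom = params.xi**2 * path.momenta[:, 1] / path.momenta[:, 0]
        core = np.s_[5:-5]
        rel = np.abs(kg_fd[core] - kg_mom[core]) / np.abs(kg_mom[core]).max()
        assert rel.max() < 1e-2

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            geodesic_curvature_gauss_bonnet(np.eye(3), [0, 1, 2])


# ---------------------------------------------------------------------------
# wavefronts
# ---------------------------------------------------------------------------

class TestWavefront:
    def test_small_time_stays_near_identity(self):
        pts = wavefront(ModelParams(1.0), 0.05, n_beta=8, n_c=5, c_cap=4.0)
        for g in pts:
            assert np.linalg.norm(g.as_array()) < 0.12

    def test_points_reproduce_their_exponential_map(self):
        params = ModelParams(1.0)
        pts, moms = wavefront(params, 0.8, n_beta=6, n_c=5, c_cap=3.0,
                              return_momenta=True)
        for g, h0 in zip(pts[::4], moms[::4]):
            path = exponential_map(h0, params, 0.8, 1)
            assert np.abs(np.sin(path.states[-1]) - np.sin(g.as_array())).max() < 1e-6
            assert np.abs(np.cos(path.states[-1]) - np.cos(g.as_array())).max() < 1e-6


def test_geodesic_path_requires_increasing_parameter():
    with pytest.raises(ValueError):
        GeodesicPath(
            states=np.zeros((3, 3)), momenta=np.zeros((3, 3)),
            param_kind="sr_arclength_t", param_values=np.array([0.0, 0.5, 0.4]),
            controls=np.zeros((3, 2)), xi=1.0,
        )
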