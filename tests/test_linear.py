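import math

import numpy as np
import pytest
import scipy.sparse as sp

from iknm import linear
from iknm.geometry import GrowthLaw, ShellGeometry


def fd_eigenvalues(rho: float, n: int, k: int) -> np.ndarray:
    """Independent finite-difference eigensolver for the radial problem.

    Conservative second-order discretization of (1/xi²)(xi² H')' = -λ² H
    with Neumann ends; returns the k smallest nonzero eigenvalues λ.
    """
    faces = np.linspace(rho, 1.0, n + 1)
    xi = 0.5 * (faces[:-1] + faces[1:])
    h = faces[1] - faces[0]
    fp = faces[1:] ** 2
    fm = faces[:-1] ** 2
    fp[-1] = 0.0   # Neumann: zero flux through the outer faces
    fm[0] = 0.0
    main = -(fp + fm) / (h**2 * xi**2)
    upr = fp[:-1] / (h**2 * xi[:-1] ** 2)
    lowr = fm[1:] / (h**2 * xi[1:] ** 2)
    A = sp.diags([lowr, main, upr], [-1, 0, 1]).toarray()
    w = np.sort(-np.linalg.eigvals(A).real)
    return np.sqrt(np.clip(w[1:k + 1], 0, None))


class TestEigenproblem:
    def test_matches_fd_oracle_to_four_digits(self, geom, eigensystem):
        # Richardson-extrapolated FD eigenvalues (h² convergence)
        lam_h = fd_eigenvalues(geom.rho, 1500, 8)
        lam_h2 = fd_eigenvalues(geom.rho, 3000, 8)
        lam_ext = (4 * lam_h2 - lam_h) / 3
        assert np.allclose(eigensystem.lambdas, lam_ext, rtol=1e-4)

    def test_ode_residual_small(self, eigensystem):
        rho = eigensystem.rho
        xi = np.linspace(rho + 1e-4, 1 - 1e-4, 2001)
        h = xi[1] - xi[0]
        for i in range(4):
            H = eigensystem.mode(i, xi)
            lap = np.gradient(xi**2 * np.gradient(H, xi), xi) / xi**2
            resid = lap + eigensystem.lambdas[i] ** 2 * H
            # central-difference truncation dominates; interior residual small
            assert np.abs(resid[5:-5]).max() < 1e-3 * np.abs(H).max() * eigensystem.lambdas[i] ** 2

    def test_neumann_ends(self, eigensystem):
        rho = eigensystem.rho
        eps = 1e-7
        for i in range(eigensystem.M):
            d_rho = (eigensystem.mode(i, rho + 2 * eps)
                     - eigensystem.mode(i, rho)) / (2 * eps) \
                - 0  # forward difference at the wall
            d_one = (eigensystem.mode(i, 1.0)
                     - eigensystem.mode(i, 1.0 - 2 * eps)) / (2 * eps)
            # O(eps·λ²) forward-difference bias; the derivative itself vanishes
            scale = eigensystem.lambdas[i] ** 2 * eps * 10
            assert abs(d_rho) < 1e-4 + scale
            assert abs(d_one) < 1e-4 + scale

    def test_orthonormal_under_xi2_weight(self, eigensystem):
        from scipy.integrate import quad
        for i in range(3):
            for j in range(i, 4):
                val = quad(lambda x: x**2
                           * eigensystem.mode(i, np.array([x]))[0]
                           * eigensystem.mode(j, np.array([x]))[0],
                           eigensystem.rho, 1.0, limit=200)[0]
                assert val == pytest.approx(1.0 if i == j else 0.0, abs=1e-8)

    def test_thin_shell_planar_limit(self):
        rho = 0.99
        es = linear.solve_eigenproblem(rho, M=4)
        planar = np.arange(1, 5) * math.pi / (1 - rho)
        assert np.allclose(es.lambdas, planar, rtol=2e-3)

    def test_eigenvalues_strictly_increasing(self, eigensystem):
        assert np.all(np.diff(eigensystem.lambdas) > 0)


class TestInfluxParams:
    def test_scaling_with_D(self, geom, growth):
        f1, s1 = linear.influx_params(geom, growth, 0.1)
        f2, s2 = linear.influx_params(geom, growth, 0.2)
        assert f2 == pytest.approx(f1 / 2)
        assert s2 == pytest.approx(s1 / 2)

    def test_apical_flux_of_solution(self, geom, growth, eigensystem):
        """The evaluated series satisfies the dimensional influx condition."""
        D = 0.17
        params, gl = _smooth_solution(geom, growth, D, eigensystem)
        a = geom.a
        for t in [0.0, 50.0, 120.0, 200.0]:
            s = float(params.s_of_t(t))
            eps = 1e-6
            dc_dxi = (linear.evaluate_linear(1.0, s, params)
                      - linear.evaluate_linear(1.0 - eps, s, params)) / eps
            lhs = D * dc_dxi[0] / a
            rhs = gl.influx_rate(t) / geom.S
            assert lhs == pytest.approx(rhs, rel=1e-3)

    def test_g0_gives_initial_mass_N0(self, geom, growth, eigensystem):
        """Volume integral of the s=0 solution equals N0 (g0 constraint)."""
        params, gl = _smooth_solution(geom, growth, 0.17, eigensystem)
        xi = np.linspace(geom.rho, 1.0, 4001)
        c0 = linear.evaluate_linear(xi, 0.0, params)
        mass = geom.Omega * geom.a**3 * np.trapezoid(xi**2 * c0, xi)
        assert mass == pytest.approx(gl.N0, rel=0.01)


def _smooth_solution(geom, growth, D, eigensystem, M=8):
    """Shared helper: solution projected from a smooth binned profile.

    The growth law's N0 is matched to the profile's mass (as in the real
    workflow, where N0 is the initial tracked count).
    """
    edges = np.linspace(geom.b, geom.a, 21)
    cen = 0.5 * (edges[:-1] + edges[1:]) / geom.a
    dxi = np.diff(edges) / geom.a
    c0 = 2e-3 * (1 + 0.8 * (cen - geom.rho) / (1 - geom.rho))
    n0 = linear.profile_mass(geom, cen, dxi, c0)
    gl = type(growth)(N0=n0, TP=growth.TP)
    return linear.build_solution(geom, gl, D, cen, dxi, c0,
                                 M=M, eigensystem=eigensystem), gl


class TestProjection:
    def test_particular_solution_projects_to_zero(self, geom, growth, eigensystem):
        """A profile equal to the s=0 particular term has h_tilde ≈ 0."""
        D = 0.17
        f0, sigma = linear.influx_params(geom, growth, D)
        g0 = linear.particular_g0(geom.rho, sigma)
        rho = geom.rho
        # fine binning so the quadrature error is small
        edges = np.linspace(rho, 1.0, 201)
        cen = 0.5 * (edges[:-1] + edges[1:])
        dxi = np.diff(edges)
        c0 = f0 * (0.5 * cen**2 - rho * cen + g0) / (1 - rho)
        h_tilde, h = linear.project_initial(cen, dxi, c0, eigensystem, f0,
                                            sigma, g0)
        assert np.abs(h_tilde).max() < 1e-3 * abs(f0)
        expected_h = -linear.alpha_coefficients(eigensystem, sigma, g0) \
            * f0 / (sigma + eigensystem.lambdas**2)
        assert np.allclose(h, expected_h, atol=1e-3 * abs(f0))

    def test_single_mode_recovered(self, geom, growth, eigensystem):
        """Particular term + H_1 projects to h_tilde = (1, 0, 0, ...)."""
        D = 0.17
        f0, sigma = linear.influx_params(geom, growth, D)
        g0 = linear.particular_g0(geom.rho, sigma)
        rho = geom.rho
        edges = np.linspace(rho, 1.0, 401)
        cen = 0.5 * (edges[:-1] + edges[1:])
        dxi = np.diff(edges)
        amp = 1e-3
        c0 = (f0 * (0.5 * cen**2 - rho * cen + g0) / (1 - rho)
              + amp * eigensystem.mode(0, cen))
        h_tilde, _ = linear.project_initial(cen, dxi, c0, eigensystem, f0,
                                            sigma, g0)
        assert h_tilde[0] == pytest.approx(amp, rel=1e-3)
        assert np.abs(h_tilde[1:]).max() < 1e-2 * amp

    def test_reconstruction_error_small(self, geom, growth, eigensystem):
        """Evaluating the projected solution at s=0 reproduces a smooth profile.

        The error floor is set by the truncation tail of the quadratic
        particular term (its apical slope violates the homogeneous Neumann
        condition of the eigenbasis, so its expansion converges slowly and
        enters scaled by f0): measured ~7% at M=8, shrinking to ~2% at M=24.
        """
        params, _ = _smooth_solution(geom, growth, 0.17, eigensystem)
        edges = np.linspace(geom.b, geom.a, 21)
        cen = 0.5 * (edges[:-1] + edges[1:]) / geom.a
        target = 2e-3 * (1 + 0.8 * (cen - geom.rho) / (1 - geom.rho))
        recon = linear.evaluate_linear(cen, 0.0, params)
        l2 = np.linalg.norm(recon - target) / np.linalg.norm(target)
        assert l2 < 0.08
        # truncation-order convergence of the same projection
        es24 = linear.solve_eigenproblem(geom.rho, M=24)
        params24, _ = _smooth_solution(geom, growth, 0.17, es24, M=24)
        recon24 = linear.evaluate_linear(cen, 0.0, params24)
        l2_24 = np.linalg.norm(recon24 - target) / np.linalg.norm(target)
        assert l2_24 < 0.03
        assert l2_24 < l2

    def test_empty_profile_rejected(self, eigensystem):
        with pytest.raises(ValueError):
            linear.project_initial(np.array([]), np.array([]), np.array([]),
                                   eigensystem, 1.0, 10.0)


class TestEvaluate:
    def test_pure_eigenmode_decay(self, geom, eigensystem):
        """With f0=0 and a single-mode IC, c = H_1 e^{-λ1² s}."""
        params = linear.LinearSolutionParams(
            eigensystem=eigensystem,
            h=np.array([1.0] + [0.0] * 7), h_tilde=np.array([1.0] + [0.0] * 7),
            alpha=np.zeros(8), f0=0.0, sigma=10.0, g0=0.0, D=0.1, a=geom.a)
        xi = np.linspace(geom.rho, 1.0, 11)
        s = 0.013
        c = linear.evaluate_linear(xi, s, params)
        expected = eigensystem.mode(0, xi) * math.exp(-eigensystem.lambdas[0] ** 2 * s)
        assert np.allclose(c, expected, rtol=1e-12)

    def test_matches_method_of_lines_oracle(self, geom, growth, eigensystem):
        """Closed form vs brute-force PDE integration: <1% over 200 min."""
        from iknm.nonlinear import solve_nonlinear
        D = 0.17
        params, gl = _smooth_solution(geom, growth, D, eigensystem)
        t = np.arange(0.0, 201.0, 10.0)
        grid = solve_nonlinear(lambda x: linear.evaluate_linear(x, 0.0, params),
                               D, np.inf, geom, gl, t, n_nodes=400)
        xi = np.linspace(geom.rho + 0.01, 0.99, 40)
        c_series = linear.evaluate_linear(xi, params.s_of_t(t), params)
        c_pde = np.stack([grid.interp(xi, tt) for tt in t])
        err = np.abs(c_series - c_pde).max() / np.abs(c_pde).max()
        assert err < 0.01

    def test_basal_no_flux(self, geom, growth, eigensystem):
        params, _ = _smooth_solution(geom, growth, 0.17, eigensystem)
        rho = geom.rho
        eps = 1e-6
        for t in [0.0, 100.0, 200.0]:
            s = float(params.s_of_t(t))
            d = (linear.evaluate_linear(rho + eps, s, params)
                 - linear.evaluate_linear(rho, s, params)) / eps
            assert abs(d[0]) < 1e-4 * linear.evaluate_linear(rho, s, params)[0] / (1 - rho)

    def test_negative_time_rejected(self, geom, growth, eigensystem):
        params, _ = _smooth_solution(geom, growth, 0.17, eigensystem)
        with pytest.raises(ValueError):
            linear.evaluate_linear(0.8, -0.1, params)


class TestDecayTimes:
    def test_inverse_proportional_to_D(self, eigensystem, geom):
        T1 = linear.decay_times(eigensystem, 0.1, geom.a)
        T2 = linear.decay_times(eigensystem, 0.2, geom.a)
        assert np.allclose(T1, 2 * T2)

    def test_strictly_decreasing(self, eigensystem, geom):
        T = linear.decay_times(eigensystem, 0.17, geom.a)
        assert np.all(np.diff(T) < 0)

    def test_thin_shell_planar_value(self):
        rho = 0.99
        a = 100.0
        D = 0.1
        es = linear.solve_eigenproblem(rho, M=2)
        T = linear.decay_times(es, D, a)
        planar_T1 = (1 - rho) ** 2 * a**2 / (math.pi**2 * D)
        assert T[0] == pytest.approx(planar_T1, rel=5e-3)
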