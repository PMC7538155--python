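"""Exact eigenfunction solution of linear diffusion in a spherical shell.

Model: the nuclear concentration c(r, t) obeys ordinary diffusion

    dc/dt = (D / r²) d/dr (r² dc/dr),        b <= r <= a,

with an exponentially growing influx through the apical surface,

    D dc/dr |_{r=a} = N0 / (S tau) * exp(t / tau),

and no flux through the basal surface, dc/dr|_{r=b} = 0.  In dimensionless
variables xi = r/a, s = D t / a², rho = b/a the solution separates into a
growing quadratic particular term plus a series over the Neumann radial
eigenmodes H_i of the spherical Laplacian:

    c(xi, s) = sum_i [ h_i e^{-lambda_i² s} + alpha_i f0 / (sigma + lambda_i²)
               e^{sigma s} ] H_i(xi)
               + f0 e^{sigma s} (xi²/2 - rho xi + g0) / (1 - rho)

with sigma = a²/(D tau) and f0 = N0 a / (S tau D).  The constant g0 follows
from mass consistency: the eigenmodes carry no net mass, so the particular
term alone must reproduce the influx, which fixes

    sigma * Int_rho^1 xi² (xi²/2 - rho xi + g0)/(1-rho) dxi = 1,

and that same condition makes the volume integral of the s = 0 particular
term equal N0/(Omega a³) identically.  The alpha_i are the xi²-weighted
projections of the residual left when the quadratic term is substituted
into the PDE.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import quad
from scipy.optimize import brentq

from .geometry import GrowthLaw, ShellGeometry

__all__ = [
    "EigenSystem",
    "LinearSolutionParams",
    "solve_eigenproblem",
    "influx_params",
    "particular_g0",
    "alpha_coefficients",
    "project_initial",
    "evaluate_linear",
    "decay_times",
]


def _mode_raw(lam: float, rho: float, xi: np.ndarray) -> np.ndarray:
    """Unnormalized eigenmode satisfying the basal Neumann condition.

    General radial solution: H = [A sin(lam xi) + B cos(lam xi)] / xi.
    H'(rho) = 0 selects (A, B) up to scale; we use the combination
    f(xi) = sin(lam (xi - rho)) * p + cos(lam (xi - rho)) * q built so that
    the derivative condition at xi = rho holds exactly.
    """
    # Write f(xi) = xi * H(xi) = C1 sin(lam(xi-rho)) + C2 cos(lam(xi-rho)).
    # H' = (lam f' xi - f)/xi^2... careful: H = f/xi, H' = (f' xi - f)/xi^2
    # with f' = d f/d xi.  At xi=rho: f'(rho) rho - f(rho) = 0.
    # f(rho) = C2, f'(rho) = lam C1  ->  C1 = C2/(lam rho).  Take C2 = 1.
    u = lam * (xi - rho)
    f = np.sin(u) / (lam * rho) + np.cos(u)
    return f / xi


def _det(lam: float, rho: float) -> float:
    """Apical Neumann condition for the basal-satisfying mode: f'(1) - f(1) = 0."""
    u = lam * (1.0 - rho)
    f1 = math.sin(u) / (lam * rho) + math.cos(u)
    fp1 = math.cos(u) / rho - lam * math.sin(u)
    return fp1 - f1


@dataclass(frozen=True)
class EigenSystem:
    """Neumann eigenmodes of the radial diffusion operator on [rho, 1].

    ``modes[i](xi)`` are normalized so that Int_rho^1 xi² H_i² dxi = 1; the
    zero eigenvalue (constant mode) is excluded — its mass bookkeeping is
    carried by the particular solution's g0.
    """

    rho: float
    lambdas: np.ndarray            # ascending, positive
    norms: np.ndarray              # of the raw (pre-normalization) modes
    M: int

    def mode(self, i: int, xi) -> np.ndarray:
        """Normalized eigenmode H_i evaluated at xi (i is 0-based)."""
        xi = np.asarray(xi, dtype=float)
        return _mode_raw(self.lambdas[i], self.rho, xi) / math.sqrt(self.norms[i])

    def modes_matrix(self, xi) -> np.ndarray:
        """Array of shape (M, len(xi)) of all normalized modes."""
        xi = np.asarray(xi, dtype=float)
        return np.stack([self.mode(i, xi) for i in range(self.M)])


def solve_eigenproblem(rho: float, M: int = 8) -> EigenSystem:
    """First ``M`` nonzero Neumann eigenvalues/eigenmodes on [rho, 1].

    The transcendental condition (apical Neumann on the basal-satisfying
    spherical mode) is bracketed by scanning lambda and solved with Brent's
    method.  Eigenvalues cluster near i*pi/(1-rho).
    """
    if not 0.0 < rho < 1.0:
        raise ValueError(f"rho must lie in (0,1), got {rho}")
    if M < 1:
        raise ValueError("M must be >= 1")
    width = 1.0 - rho
    lambdas = []
    # scan in steps well below the pi/width eigenvalue spacing
    step = math.pi / width / 40.0
    lam = step * 1e-3
    prev = _det(lam, rho)
    prev_lam = lam
    # upper scan bound: comfortably past the M-th planar-limit eigenvalue
    lam_max = (M + 2) * math.pi / width
    while len(lambdas) < M:
        lam += step
        if lam > lam_max:
            raise RuntimeError(
                f"eigenvalue bracketing failed: found {len(lambdas)} roots "
                f"scanning (0, {lam_max:.3f}] for rho={rho}"
            )
        cur = _det(lam, rho)
        if prev == 0.0:
            lambdas.append(prev_lam)
        elif prev * cur < 0.0:
            root = brentq(_det, prev_lam, lam, args=(rho,), xtol=1e-14, rtol=1e-14)
            lambdas.append(root)
        prev, prev_lam = cur, lam
    lambdas = np.array(lambdas[:M])
    norms = np.empty(M)
    for i, l in enumerate(lambdas):
        norms[i] = quad(lambda x: x**2 * _mode_raw(l, rho, np.array([x]))[0] ** 2,
                        rho, 1.0, limit=200)[0]
    return EigenSystem(rho=rho, lambdas=lambdas, norms=norms, M=M)


def influx_params(geometry: ShellGeometry, growth: GrowthLaw, D: float
                  ) -> tuple[float, float]:
    """Dimensionless influx amplitude f0 and growth rate sigma.

    From the apical flux condition D dc/dr|_a = N0/(S tau) e^{t/tau} written
    in xi = r/a, s = D t/a²:  dc/dxi|_1 = f0 e^{sigma s} with

        sigma = a² / (D tau),     f0 = N0 a / (S tau D).

    f0 carries concentration units (µm⁻³), so the evaluated solution is
    dimensional directly.
    """
    if D <= 0:
        raise ValueError("D must be positive")
    a = geometry.a
    sigma = a**2 / (D * growth.tau)
    f0 = growth.N0 * a / (geometry.S * growth.tau * D)
    return f0, sigma


def particular_g0(rho: float, sigma: float) -> float:
    """Constant g0 of the quadratic particular term.

    Fixed by requiring sigma * Int xi² u dxi = 1 for
    u = (xi²/2 - rho xi + g0)/(1-rho), i.e. mass growth of the particular
    term matches the apical influx (the eigenmodes are massless).
    """
    I_poly = (1.0 - rho**5) / 10.0 - rho * (1.0 - rho**4) / 4.0
    return 3.0 / (1.0 - rho**3) * ((1.0 - rho) / sigma - I_poly)


def _residual(xi: np.ndarray, rho: float, sigma: float, g0: float) -> np.ndarray:
    """PDE residual of the quadratic particular term (per unit f0 e^{sigma s}).

    R = sigma*u - Laplacian(u) with u = (xi²/2 - rho xi + g0)/(1-rho) and
    Laplacian u = (3 - 2 rho/xi)/(1-rho).
    """
    u = (0.5 * xi**2 - rho * xi + g0) / (1.0 - rho)
    return sigma * u - (3.0 - 2.0 * rho / xi) / (1.0 - rho)


def alpha_coefficients(eigensystem: EigenSystem, sigma: float, g0: float
                       ) -> np.ndarray:
    """Projections alpha_i = -<R, H_i>_{xi²} of the particular-term residual.

    These make the full series satisfy the PDE: the eigen-part absorbs the
    residual the growing quadratic term leaves behind.
    """
    rho = eigensystem.rho
    alphas = np.empty(eigensystem.M)
    for i in range(eigensystem.M):
        integrand = lambda x: (x**2 * _residual(np.array([x]), rho, sigma, g0)[0]
                               * eigensystem.mode(i, np.array([x]))[0])
        alphas[i] = -quad(integrand, rho, 1.0, limit=200)[0]
    return alphas


@dataclass(frozen=True)
class LinearSolutionParams:
    """Everything needed to evaluate the closed-form solution."""

    eigensystem: EigenSystem
    h: np.ndarray          # decaying-mode coefficients
    h_tilde: np.ndarray    # raw data projections (h + alpha f0/(sigma+lam²))
    alpha: np.ndarray
    f0: float              # µm^-3
    sigma: float
    g0: float
    D: float               # µm²/min
    a: float               # µm

    def s_of_t(self, t_min) -> np.ndarray:
        return np.asarray(t_min, dtype=float) * self.D / self.a**2


def project_initial(xi_centers: np.ndarray, dxi: np.ndarray, c0: np.ndarray,
                    eigensystem: EigenSystem, f0: float, sigma: float,
                    g0: float | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Project a binned initial concentration profile onto the eigenmodes.

    h_tilde_i = sum_m xi_m² H_i(xi_m) c(xi_m) dxi_m
                - f0/(1-rho) * Int_rho^1 xi² H_i (xi²/2 - rho xi + g0) dxi,

    (a midpoint-rule projection of the data minus the exact projection of the
    particular term), then h_i = h_tilde_i - alpha_i f0 / (sigma + lambda_i²).

    Returns (h_tilde, h).
    """
    xi_centers = np.asarray(xi_centers, dtype=float)
    dxi = np.asarray(dxi, dtype=float)
    c0 = np.asarray(c0, dtype=float)
    if xi_centers.size == 0:
        raise ValueError("empty initial profile")
    rho = eigensystem.rho
    if g0 is None:
        g0 = particular_g0(rho, sigma)
    alphas = alpha_coefficients(eigensystem, sigma, g0)
    h_tilde = np.empty(eigensystem.M)
    for i in range(eigensystem.M):
        data_term = np.sum(xi_centers**2 * eigensystem.mode(i, xi_centers)
                           * c0 * dxi)
        integrand = lambda x: (x**2 * eigensystem.mode(i, np.array([x]))[0]
                               * (0.5 * x**2 - rho * x + g0))
        part_term = f0 / (1.0 - rho) * quad(integrand, rho, 1.0, limit=200)[0]
        h_tilde[i] = data_term - part_term
    h = h_tilde - alphas * f0 / (sigma + eigensystem.lambdas**2)
    return h_tilde, h


def profile_mass(geometry: ShellGeometry, xi_centers: np.ndarray,
                 dxi: np.ndarray, c: np.ndarray) -> float:
    """Nucleus count carried by a binned profile (exact shell-bin volumes)."""
    xi_centers = np.asarray(xi_centers, dtype=float)
    dxi = np.asarray(dxi, dtype=float)
    lo = xi_centers - dxi / 2
    hi = xi_centers + dxi / 2
    V = geometry.Omega * geometry.a**3 / 3.0 * (hi**3 - lo**3)
    return float(np.sum(np.asarray(c, dtype=float) * V))


def build_solution(geometry: ShellGeometry, growth: GrowthLaw, D: float,
                   xi_centers: np.ndarray, dxi: np.ndarray, c0: np.ndarray,
                   M: int = 8, eigensystem: EigenSystem | None = None
                   ) -> LinearSolutionParams:
    """Assemble the full closed-form solution from a binned initial profile.

    The eigenbasis carries no net mass, so the expansion can only represent
    initial profiles whose volume integral equals N0 — which holds by
    construction when N0 is the initial tracked count, the quantity the
    growth law is built from.  A mismatch beyond 5% triggers a warning: the
    reconstruction would then be off by the (unrepresentable) constant mode.
    """
    if eigensystem is None:
        eigensystem = solve_eigenproblem(geometry.rho, M=M)
    m0 = profile_mass(geometry, xi_centers, dxi, c0)
    if abs(m0 - growth.N0) > 0.05 * growth.N0:
        warnings.warn(
            f"initial profile carries {m0:.1f} nuclei but growth.N0={growth.N0}; "
            "the mass mismatch cannot be represented by the eigenmodes",
            RuntimeWarning, stacklevel=2)
    f0, sigma = influx_params(geometry, growth, D)
    g0 = particular_g0(eigensystem.rho, sigma)
    alphas = alpha_coefficients(eigensystem, sigma, g0)
    h_tilde, h = project_initial(xi_centers, dxi, c0, eigensystem, f0, sigma, g0)
    return LinearSolutionParams(eigensystem=eigensystem, h=h, h_tilde=h_tilde,
                                alpha=alphas, f0=f0, sigma=sigma, g0=g0, D=D,
                                a=geometry.a)


def evaluate_linear(xi, s, params: LinearSolutionParams) -> np.ndarray:
    """Evaluate c(xi, s) (µm⁻³). ``xi`` and ``s`` broadcast to (len(s), len(xi)).

    s may be a scalar or array; s < 0 is rejected.
    """
    xi = np.atleast_1d(np.asarray(xi, dtype=float))
    s_arr = np.atleast_1d(np.asarray(s, dtype=float))
    if np.any(s_arr < 0):
        raise ValueError("dimensionless time s must be non-negative")
    es = params.eigensystem
    rho = es.rho
    if np.any(xi < rho - 1e-9) or np.any(xi > 1.0 + 1e-9):
        raise ValueError("xi outside [rho, 1]")
    H = es.modes_matrix(xi)                       # (M, nxi)
    lam2 = es.lambdas**2                           # (M,)
    # coefficients per time: (ns, M)
    decay = params.h[None, :] * np.exp(-lam2[None, :] * s_arr[:, None])
    grow = (params.alpha[None, :] * params.f0 / (params.sigma + lam2)[None, :]
            * np.exp(params.sigma * s_arr)[:, None])
    series = (decay + grow) @ H                    # (ns, nxi)
    u = (0.5 * xi**2 - rho * xi + params.g0) / (1.0 - rho)
    part = params.f0 * np.exp(params.sigma * s_arr)[:, None] * u[None, :]
    out = series + part
    if np.isscalar(s) or np.asarray(s).ndim == 0:
        return out[0]
    return out


def evaluate_linear_gradient(xi, s, params: LinearSolutionParams,
                             eps: float = 1e-6) -> np.ndarray:
    """dc/dxi by central differences of the closed form (one-sided at ends)."""
    xi = np.atleast_1d(np.asarray(xi, dtype=float))
    rho = params.eigensystem.rho
    lo = np.clip(xi - eps, rho, 1.0)
    hi = np.clip(xi + eps, rho, 1.0)
    c_lo = evaluate_linear(lo, s, params)
    c_hi = evaluate_linear(hi, s, params)
    return (c_hi - c_lo) / (hi - lo)


def decay_times(eigensystem: EigenSystem, D: float, a: float) -> np.ndarray:
    """Decay times T_i = a² / (D lambda_i²) of the eigenmodes, min."""
    if D <= 0:
        raise ValueError("D must be positive")
    return a**2 / (D * eigensystem.lambdas**2)
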