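"""Equilibrium axisymmetric cell-membrane shapes around a spherical nucleus.

The elongated cell enveloping a nucleus is modelled as an axisymmetric
membrane delta(z) carrying bending energy (modulus kappa) and surface
tension gamma,

    E = Int dS [ kappa/2 H² + gamma ],   dS = 2 pi delta sqrt(1 + delta_z²),

whose stationary shapes obey the shape equation

    -gamma H + 2 kappa (H³ - K H) + kappa Lap H = 0,

with the axisymmetric mean curvature
H = delta_zz/(1+delta_z²)^{3/2} - 1/(delta sqrt(1+delta_z²)), Gaussian
curvature K = -delta_zz/(delta (1+delta_z²)²) and surface Laplacian
Lap = (1/(delta s)) d/dz (delta/s d/dz), s = sqrt(1+delta_z²).

Near the nucleus the membrane is assumed to wrap it as a spherical arc of
radius Rtube = R + gap; the free region is solved as a fourth-order boundary
value problem on [0, z_contact] and z_contact is iterated until delta,
delta_z and the mean curvature are continuous through the contact point.
Note the curvature convention: H of a sphere of radius Rtube evaluated with
the formula above is -2/Rtube, twice the "circle" value -1/Rtube sometimes
quoted; the matching target is configurable (``contact_curvature``).

All lengths in µm; energies in units of kappa (set gamma in kappa/µm²).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_bvp
from scipy.optimize import brentq

__all__ = ["MembraneParams", "CellShape", "mean_curvature",
           "gaussian_curvature", "solve_shape", "shape_energy"]


def mean_curvature(delta, delta_z, delta_zz):
    """Axisymmetric mean curvature H(δ, δ', δ'')."""
    delta = np.asarray(delta, dtype=float)
    delta_z = np.asarray(delta_z, dtype=float)
    delta_zz = np.asarray(delta_zz, dtype=float)
    s2 = 1.0 + delta_z**2
    return delta_zz / s2**1.5 - 1.0 / (delta * np.sqrt(s2))


def gaussian_curvature(delta, delta_z, delta_zz):
    """Axisymmetric Gaussian curvature K(δ, δ', δ'')."""
    delta = np.asarray(delta, dtype=float)
    delta_z = np.asarray(delta_z, dtype=float)
    delta_zz = np.asarray(delta_zz, dtype=float)
    return -delta_zz / (delta * (1.0 + delta_z**2) ** 2)


@dataclass(frozen=True)
class MembraneParams:
    """Cell and nucleus geometry plus membrane moduli (kappa units)."""

    delta_a: float = 1.98       # µm, apical cell radius
    delta_b: float = 0.94       # µm, basal cell radius
    L: float = 55.0             # µm, cell length
    R: float = 3.5              # µm, nuclear radius
    gamma: float = 2.0          # kappa/µm², tension (demonstration scale)
    nucleus_z: float | None = None   # default mid-cell
    gap: float = 0.0            # µm, membrane-nucleus gap
    contact_curvature: str = "eq_arc"   # "eq_arc" (-2/Rtube) | "half" (-1/Rtube)

    def __post_init__(self) -> None:
        if min(self.delta_a, self.delta_b, self.L, self.R) <= 0:
            raise ValueError("all lengths must be positive")
        if self.R >= self.L / 2:
            raise ValueError("nucleus must fit inside the cell (R < L/2)")
        if self.gap < 0:
            raise ValueError("gap must be non-negative")
        if self.contact_curvature not in ("eq_arc", "half"):
            raise ValueError("contact_curvature must be 'eq_arc' or 'half'")

    @property
    def Rtube(self) -> float:
        return self.R + self.gap

    @property
    def z_nucleus(self) -> float:
        return self.L / 2 if self.nucleus_z is None else self.nucleus_z


@dataclass(frozen=True)
class CellShape:
    """Composite equilibrium shape: two free regions joined by the arc."""

    z_samples: np.ndarray     # µm, over [0, L]
    delta: np.ndarray         # µm
    H: np.ndarray             # 1/µm, mean curvature along z
    z_contact: tuple[float, float]   # apical-side and basal-side contacts
    energy: float             # kappa units
    continuity_residual: float       # max |jump| in (δ, δ_z) at the contacts


def _rhs(gamma_kappa: float):
    def fun(z, y):
        d, dz, H, Q = y
        s2 = 1.0 + dz**2
        dzz = s2**1.5 * H + s2 / d
        K = -dzz / (d * s2**2)
        lapH = gamma_kappa * H - 2.0 * (H**3 - K * H)
        return np.vstack([dz,
                          dzz,
                          Q * np.sqrt(s2) / d,
                          d * np.sqrt(s2) * lapH])
    return fun


def _arc(z: np.ndarray, z_nuc: float, Rtube: float) -> np.ndarray:
    return np.sqrt(np.maximum(Rtube**2 - (z - z_nuc) ** 2, 0.0))


def _solve_free(delta_end: float, z_nuc: float, Rtube: float,
                gamma_kappa: float, zc: float):
    """Free-region BVP on [0, zc]: flat at the cell end, arc-matched at zc.

    Returns the solve_bvp solution (or raises RuntimeError).
    Continuation in gamma from an easy value stabilizes large tensions.
    """
    d_c = _arc(np.array([zc]), z_nuc, Rtube)[0]
    dz_c = -(zc - z_nuc) / d_c

    def bc(ya, yb):
        return np.array([ya[0] - delta_end, ya[1],
                         yb[0] - d_c, yb[1] - dz_c])

    def guess(n):
        z0 = np.linspace(0, zc, n)
        d0 = delta_end + (d_c - delta_end) * (z0 / zc) ** 2
        y0 = np.vstack([d0, np.gradient(d0, z0),
                        -1.0 / d0, np.zeros_like(z0)])
        return z0, y0

    # direct solve from a smooth quadratic guess; continuation in gamma as a
    # fallback for stiff (large-tension) cases
    res = solve_bvp(_rhs(gamma_kappa), bc, *guess(201), max_nodes=50000,
                    tol=1e-8)
    if res.success:
        return res
    sol = None
    for g in np.geomspace(1.0, gamma_kappa, 8):
        z0, y0 = guess(201) if sol is None else (sol.x, sol.y)
        res = solve_bvp(_rhs(g), bc, z0, y0, max_nodes=50000, tol=1e-8)
        if not res.success:
            raise RuntimeError(
                f"free-region BVP failed at gamma={g:g}: {res.message}")
        sol = res
    return sol


def _match_half(delta_end: float, z_nuc: float, Rtube: float,
                gamma_kappa: float, target_H: float) -> tuple[float, object]:
    """Find z_contact such that H is continuous through the junction."""

    def mismatch(zc: float) -> float:
        sol = _solve_free(delta_end, z_nuc, Rtube, gamma_kappa, zc)
        return sol.y[2, -1] - target_H

    lo = z_nuc - 0.95 * Rtube
    hi = z_nuc - 0.05 * Rtube
    # bracket by scanning
    zs = np.linspace(lo, hi, 13)
    vals = []
    for z in zs:
        try:
            vals.append(mismatch(z))
        except RuntimeError:
            vals.append(np.nan)
    vals = np.array(vals)
    ok = np.isfinite(vals)
    br = None
    for i in range(zs.size - 1):
        if ok[i] and ok[i + 1] and vals[i] * vals[i + 1] < 0:
            br = (zs[i], zs[i + 1])
            break
    if br is None:
        raise RuntimeError(
            "no z_contact with continuous curvature found; mismatch over "
            f"[{lo:.2f}, {hi:.2f}] = {np.array2string(vals, precision=3)}")
    zc = brentq(mismatch, br[0], br[1], xtol=1e-10)
    return zc, _solve_free(delta_end, z_nuc, Rtube, gamma_kappa, zc)


def solve_shape(params: MembraneParams, n_out: int = 400) -> CellShape:
    """Equilibrium shape with a bulge over the nucleus and matched necks.

    Solves the apical-side free region on [0, zc_a] and the basal-side free
    region (mirrored coordinate) on [0, zc_b], joins them with the spherical
    arc of radius Rtube about the nucleus centre, and reports the composite
    profile, its mean curvature and total energy.
    """
    Rt = params.Rtube
    zn = params.z_nucleus
    target = -2.0 / Rt if params.contact_curvature == "eq_arc" else -1.0 / Rt
    # apical half (z from 0), nucleus centre at zn
    zc_a, sol_a = _match_half(params.delta_a, zn, Rt, params.gamma, target)
    # basal half in mirrored coordinate w = L - z, nucleus centre at L - zn
    zc_b_m, sol_b = _match_half(params.delta_b, params.L - zn, Rt,
                                params.gamma, target)
    zc_b = params.L - zc_b_m

    z_a = np.linspace(0, zc_a, n_out)
    z_arc = np.linspace(zc_a, zc_b, n_out)
    z_b = np.linspace(zc_b, params.L, n_out)
    ya = sol_a.sol(z_a)
    yb_m = sol_b.sol(params.L - z_b[::-1])     # mirrored evaluation
    d_arc = _arc(z_arc, zn, Rt)
    H_arc = np.full_like(z_arc, -2.0 / Rt)

    delta = np.concatenate([ya[0], d_arc[1:-1], yb_m[0][::-1]])
    H = np.concatenate([ya[2], H_arc[1:-1], yb_m[2][::-1]])
    z = np.concatenate([z_a, z_arc[1:-1], z_b])

    # continuity diagnostics at both junctions
    res = max(
        abs(ya[0, -1] - _arc(np.array([zc_a]), zn, Rt)[0]),
        abs(ya[1, -1] - (-(zc_a - zn) / _arc(np.array([zc_a]), zn, Rt)[0])),
        abs(yb_m[0, -1] - _arc(np.array([zc_b_m]), params.L - zn, Rt)[0]),
        abs(yb_m[1, -1] - (-(zc_b_m - (params.L - zn))
                           / _arc(np.array([zc_b_m]), params.L - zn, Rt)[0])),
    )
    dz = np.gradient(delta, z)
    energy = _energy_profile(z, delta, H, params.gamma)
    return CellShape(z_samples=z, delta=delta, H=H,
                     z_contact=(zc_a, zc_b), energy=energy,
                     continuity_residual=float(res))


def _energy_profile(z: np.ndarray, delta: np.ndarray, H: np.ndarray,
                    gamma: float, kappa: float = 1.0) -> float:
    dz = np.gradient(delta, z)
    integrand = 2 * math.pi * delta * np.sqrt(1 + dz**2) * (
        0.5 * kappa * H**2 + gamma)
    return float(np.trapezoid(integrand, z))


def shape_energy(shape: CellShape, kappa: float = 1.0,
                 gamma: float | None = None) -> float:
    """Bending + tension energy of a composite shape by quadrature.

    With ``gamma=None`` the energy stored at solve time is returned.
    """
    if gamma is None:
        return shape.energy
    return _energy_profile(shape.z_samples, shape.delta, shape.H, gamma, kappa)
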