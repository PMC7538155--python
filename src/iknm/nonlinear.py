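"""Nonlinear (lattice-gas) diffusion of nuclei in a spherical shell.

Steric exclusion between finite-size nuclei modifies the entropy of the
nuclear "gas" and yields the nonlinear diffusion equation

    dc/dt = (D / r²) d/dr [ r² cmax/(cmax - c) dc/dr ],

with a crowding-corrected apical influx

    D cmax/(cmax - c) dc/dr |_{r=a} = N0/(S tau) e^{t/tau}

and basal no-flux.  As c -> 0 (or cmax -> infinity) ordinary diffusion is
recovered.  The solver is a conservative method-of-lines discretization:
fluxes live on cell faces of a uniform radial grid, the spherical metric r²
is carried exactly through the finite-volume cell factors (r_+³ - r_-³)/3,
and the boundary fluxes are imposed directly — so discrete mass balance
holds to solver tolerance.  Stiff time integration by LSODA with a
tridiagonal Jacobian band.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.integrate import solve_ivp

from .geometry import GrowthLaw, ShellGeometry

__all__ = ["PDEGrid", "ClosePackingError", "solve_nonlinear", "model_gradient"]

#: relative proximity to cmax treated as a close-packing singularity
CLOSE_PACK_RTOL = 1e-6


class ClosePackingError(RuntimeError):
    """Concentration reached the close-packing singularity."""


@dataclass(frozen=True)
class PDEGrid:
    """Numerical solution c(t, xi) of the (non)linear diffusion model."""

    xi_nodes: np.ndarray     # cell centres on [rho, 1]
    t_nodes: np.ndarray      # min
    c_values: np.ndarray     # (nt, nxi), µm^-3
    D: float                 # µm²/min
    cmax: float              # µm^-3; np.inf -> linear limit
    geometry: ShellGeometry

    def interp(self, xi, t) -> np.ndarray:
        """c at (xi, t): linear interpolation in both variables."""
        xi = np.asarray(xi, dtype=float)
        t = float(t)
        if t < self.t_nodes[0] - 1e-9 or t > self.t_nodes[-1] + 1e-9:
            raise ValueError(f"t={t} outside solved window")
        k = np.searchsorted(self.t_nodes, t)
        k = min(max(k, 1), len(self.t_nodes) - 1)
        t0, t1 = self.t_nodes[k - 1], self.t_nodes[k]
        w = 0.0 if t1 == t0 else (t - t0) / (t1 - t0)
        row = (1 - w) * self.c_values[k - 1] + w * self.c_values[k]
        return np.interp(xi, self.xi_nodes, row)

    def mass(self) -> np.ndarray:
        """Total nucleus count at each output time (exact cell volumes)."""
        g = self.geometry
        faces = _faces_from_centres(self.xi_nodes, g.rho) * g.a
        Vcell = g.Omega / 3.0 * np.diff(faces**3)
        return self.c_values @ Vcell


def _faces_from_centres(centres: np.ndarray, rho: float) -> np.ndarray:
    faces = np.empty(centres.size + 1)
    faces[1:-1] = 0.5 * (centres[:-1] + centres[1:])
    faces[0] = rho
    faces[-1] = 1.0
    return faces


def solve_nonlinear(ic: Callable[[np.ndarray], np.ndarray] | np.ndarray,
                    D: float, cmax: float,
                    geometry: ShellGeometry, growth: GrowthLaw,
                    t_grid: np.ndarray,
                    influx: str = "on",
                    n_nodes: int = 400,
                    rtol: float = 1e-7, atol: float = 1e-12) -> PDEGrid:
    """Integrate the lattice-gas diffusion model.

    Parameters
    ----------
    ic : callable xi -> c (µm⁻³) or array of values on the cell centres.
    D : diffusivity, µm²/min.
    cmax : close-packing concentration, µm⁻³ (``np.inf`` recovers the linear
        model exactly).
    influx : "on" applies the apical growth flux; "off" (drug-block scenario)
        seals the apical surface.
    t_grid : output times in min, starting at 0.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid[0] != 0.0:
        raise ValueError("t_grid must start at 0")
    if influx not in ("on", "off"):
        raise ValueError("influx must be 'on' or 'off'")
    if D <= 0:
        raise ValueError("D must be positive")
    a, b = geometry.a, geometry.b
    faces_r = np.linspace(b, a, n_nodes + 1)
    centres_r = 0.5 * (faces_r[:-1] + faces_r[1:])
    dr = faces_r[1] - faces_r[0]

    if callable(ic):
        c0 = np.asarray(ic(centres_r / a), dtype=float)
    else:
        c0 = np.asarray(ic, dtype=float)
        if c0.shape != centres_r.shape:
            raise ValueError("ic array must match the cell-centre grid")
    if np.isfinite(cmax) and np.any(c0 >= cmax):
        raise ValueError("initial condition must lie strictly below cmax")

    S = geometry.S
    r2_inner = faces_r[1:-1] ** 2
    # exact finite-volume cell factor: integral of r² over the cell
    cell_vol = np.diff(faces_r**3) / 3.0
    enh_inf = np.isinf(cmax)
    influx_on = influx == "on" and not growth.divisions_absent

    def rhs(t: float, c: np.ndarray) -> np.ndarray:
        if not enh_inf and np.any(c >= cmax * (1.0 - CLOSE_PACK_RTOL)):
            raise ClosePackingError(
                f"concentration reached close packing at t={t:.3f} min")
        grad = (c[1:] - c[:-1]) / dr
        if enh_inf:
            enh = 1.0
        else:
            cf = 0.5 * (c[1:] + c[:-1])
            enh = cmax / (cmax - cf)
        # r²·(flux density) on every face; boundary fluxes imposed
        r2J = np.zeros(c.size + 1)
        r2J[1:-1] = r2_inner * D * enh * grad
        if influx_on:
            r2J[-1] = a**2 * growth.influx_rate(t) / S
        return np.diff(r2J) / cell_vol

    try:
        sol = solve_ivp(rhs, (0.0, float(t_grid[-1])), c0, method="LSODA",
                        t_eval=t_grid, rtol=rtol, atol=atol, lband=1, uband=1)
    except ClosePackingError:
        raise
    if not sol.success:
        raise RuntimeError(f"PDE integration failed: {sol.message}")
    c_values = sol.y.T
    if np.isfinite(cmax) and np.any(c_values >= cmax):
        raise ClosePackingError("close-packing singularity in output")
    return PDEGrid(xi_nodes=centres_r / a, t_nodes=t_grid, c_values=c_values,
                   D=D, cmax=cmax, geometry=geometry)


def model_gradient(grid: PDEGrid, xi, t) -> np.ndarray:
    """dc/dxi at (xi, t): centred differences on the solver grid, interpolated."""
    xi = np.asarray(xi, dtype=float)
    rho = grid.geometry.rho
    if np.any(xi < rho - 1e-9) or np.any(xi > 1.0 + 1e-9):
        raise ValueError("xi outside [rho, 1]")
    row = grid.interp(grid.xi_nodes, t)
    g = np.gradient(row, grid.xi_nodes)
    return np.interp(xi, grid.xi_nodes, g)
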