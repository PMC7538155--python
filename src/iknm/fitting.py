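"""Minimal-χ² estimation of the effective diffusion constant D.

The data are binned concentration profiles with uncertainties in both the
concentration (sigma_y, from the bin-count model) and the bin position
(sigma_x).  The x-uncertainty is folded into an effective variance through
the local model slope,

    sigma_m² = sigma_y,m² + [sigma_x,m * dc/dxi|_m]²,

and χ² = sum_m (c_exp,m - c_model,m)² / sigma_m² is evaluated on a discrete
grid of D values (no continuous optimizer — the χ²(D) curve itself is the
diagnostic).  Pooled fits sum the per-time-point χ²(D) curves; the curvature
of the summed curve at its minimum yields the standard deviation sigma_D,
and the upper tail probability P(χ²; ν) grades goodness of fit (≈ 0.5 for a
correct model with honest error bars).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import stats

from .geometry import GrowthLaw, ShellGeometry
from .linear import build_solution, evaluate_linear, evaluate_linear_gradient, solve_eigenproblem
from .nonlinear import model_gradient, solve_nonlinear
from .profile import BinSpec, ConcentrationProfile

__all__ = [
    "FitResult",
    "chi2",
    "scan_D",
    "sigma_D",
    "p_chi",
    "select_binning",
    "welch_test",
    "DEFAULT_GRID",
]

#: default scan grid, µm²/min
DEFAULT_GRID = np.arange(0.01, 10.0 + 1e-9, 0.01)


@dataclass(frozen=True)
class FitResult:
    """Outcome of a grid scan for D."""

    D_star: float           # µm²/min
    sigma_D: float          # µm²/min
    chi2: float
    nu: int
    P_chi: float
    grid: np.ndarray
    chi2_curve: np.ndarray  # χ²(D) (pooled scope: averaged over time points)
    scope: str              # "single" | "pooled"
    boundary_minimum: bool = False
    tie_broken: bool = False

    @property
    def chi2_red(self) -> float:
        return self.chi2 / self.nu


def chi2(profile: ConcentrationProfile,
         model_curve: np.ndarray,
         model_gradient_values: np.ndarray) -> tuple[float, int]:
    """Effective-variance χ² of a model curve against one profile.

    ``model_curve`` and ``model_gradient_values`` are the model concentration
    and its xi-derivative at the profile's (fit-masked) bin centres.
    ν = number of fitted bins − 1 (one fitted parameter, D).
    """
    m = profile.fit_mask
    c_exp = profile.c[m]
    sy = profile.sigma_y[m]
    sx = profile.sigma_x[m]
    var = sy**2 + (sx * np.asarray(model_gradient_values)) ** 2
    if np.any(var <= 0):
        raise ValueError("degenerate weight: sigma_m = 0 in some bin")
    value = float(np.sum((c_exp - np.asarray(model_curve)) ** 2 / var))
    nu = int(c_exp.size - 1)
    return value, nu


def _chi2_curve_nonlinear(profiles, D_grid, cmax, geometry, growth, ic,
                          n_nodes):
    from .nonlinear import ClosePackingError
    times = np.array([p.t for p in profiles])
    t_grid = np.unique(np.concatenate([[0.0], times]))
    curves = np.zeros((D_grid.size, len(profiles)))
    ic_safe = (lambda x: np.minimum(ic(x), 0.98 * cmax)) if np.isfinite(cmax) \
        else ic
    for j, D in enumerate(D_grid):
        try:
            grid = solve_nonlinear(ic_safe, D, cmax, geometry, growth, t_grid,
                                   influx="on", n_nodes=n_nodes)
        except ClosePackingError:
            # this D drives the model into the packing singularity before the
            # end of the window: it cannot describe the data
            curves[j, :] = np.inf
            continue
        for k, p in enumerate(profiles):
            xi = p.xi_centers[p.fit_mask]
            c_mod = grid.interp(xi, p.t)
            g_mod = model_gradient(grid, xi, p.t)
            curves[j, k], _ = chi2(p, c_mod, g_mod)
    return curves


def _chi2_curve_linear(profiles, D_grid, geometry, growth, ic_profile, M):
    es = solve_eigenproblem(geometry.rho, M=M)
    p0 = ic_profile
    curves = np.zeros((D_grid.size, len(profiles)))
    for j, D in enumerate(D_grid):
        params = build_solution(geometry, growth, D,
                                p0.xi_centers, p0.dxi, p0.c, M=M,
                                eigensystem=es)
        for k, p in enumerate(profiles):
            xi = p.xi_centers[p.fit_mask]
            s = params.s_of_t(p.t)
            c_mod = evaluate_linear(xi, float(s), params)
            g_mod = evaluate_linear_gradient(xi, float(s), params)
            curves[j, k], _ = chi2(p, c_mod, g_mod)
    return curves


def scan_D(profiles: Sequence[ConcentrationProfile],
           geometry: ShellGeometry,
           growth: GrowthLaw,
           model: str = "nonlinear",
           cmax: float = 4.12e-3,
           grid: np.ndarray | None = None,
           scope: str = "pooled",
           ic: Callable[[np.ndarray], np.ndarray] | None = None,
           M: int = 8,
           n_nodes: int = 200) -> FitResult:
    """Grid-scan χ²(D) for the chosen model and locate the minimum.

    For each D the model is solved from a common initial condition (by
    default the closed-form linear initial profile projected from the first
    profile, keeping linear and nonlinear fits comparable) and χ² accumulated
    over profiles.  ``scope="pooled"`` reports the per-time-point average
    χ² at the summed-curve minimum; ``scope="single"`` requires exactly one
    profile.  Grid ties are broken toward smaller D and flagged, as is a
    minimum at a grid boundary.
    """
    if grid is None:
        grid = DEFAULT_GRID
    grid = np.asarray(grid, dtype=float)
    if len(profiles) == 0:
        raise ValueError("need at least one profile")
    if scope == "single" and len(profiles) != 1:
        raise ValueError("single scope requires exactly one profile")
    p0 = profiles[0]
    if ic is None:
        # project the first profile through the linear solution at s=0
        # (evaluated at any positive D; the s=0 profile is D-independent up
        # to the f0/σ-scaled particular term, so use a mid-grid D)
        D_ref = float(np.median(grid))
        params0 = build_solution(geometry, growth, D_ref,
                                 p0.xi_centers, p0.dxi, p0.c, M=M)
        ic = lambda x: np.clip(evaluate_linear(x, 0.0, params0), 0.0, None)
    if model == "nonlinear":
        curves = _chi2_curve_nonlinear(profiles, grid, cmax, geometry, growth,
                                       ic, n_nodes)
    elif model == "linear":
        curves = _chi2_curve_linear(profiles, grid, geometry, growth, p0, M)
    else:
        raise ValueError("model must be 'linear' or 'nonlinear'")
    total = curves.sum(axis=1)
    j_star = int(np.argmin(total))  # argmin takes the first (smallest D) tie
    ties = np.flatnonzero(total == total[j_star])
    tie_broken = ties.size > 1
    boundary = j_star in (0, grid.size - 1)
    if boundary:
        warnings.warn("chi2 minimum attained at a grid boundary",
                      RuntimeWarning, stacklevel=2)
    ntp = len(profiles)
    chi2_curve = total / ntp if scope == "pooled" else total
    # degrees of freedom from the (common) number of fitted bins
    nu = int(profiles[0].fit_mask.sum() - 1)
    chi2_at_min = float(chi2_curve[j_star])
    # sigma_D from the time-AVERAGED curve (pooled scope): its delta-chi2 = 1
    # width is sqrt(n_timepoints) times the summed-curve width, which absorbs
    # the correlation between successive profiles of the same nuclei
    if boundary or not np.isfinite(
            chi2_curve[max(j_star - 1, 0):j_star + 2]).all():
        sD = float("nan")
    else:
        sD = sigma_D(chi2_curve, j_star, float(grid[1] - grid[0]))
    return FitResult(D_star=float(grid[j_star]), sigma_D=sD,
                     chi2=chi2_at_min, nu=nu,
                     P_chi=p_chi(chi2_at_min, nu),
                     grid=grid, chi2_curve=chi2_curve, scope=scope,
                     boundary_minimum=boundary, tie_broken=tie_broken)


def sigma_D(chi2_curve: np.ndarray, j_star: int, delta_D: float) -> float:
    """Standard deviation of D* from the curvature of χ²(D) at its minimum.

    Quadratic approximation of the Δχ² = 1 width:
    sigma_D = ΔD sqrt(2 / (χ²(D*-ΔD) - 2 χ²(D*) + χ²(D*+ΔD))).
    """
    if j_star <= 0 or j_star >= len(chi2_curve) - 1:
        raise ValueError("D* must be interior to the grid")
    second = (chi2_curve[j_star - 1] - 2.0 * chi2_curve[j_star]
              + chi2_curve[j_star + 1])
    if second <= 0:
        raise ValueError("non-positive second difference: no local minimum")
    return float(delta_D * math.sqrt(2.0 / second))


def p_chi(chi2_value: float, nu: int) -> float:
    """Upper-tail probability P(χ² >= chi2_value) for ν degrees of freedom."""
    if nu < 1:
        raise ValueError("nu must be >= 1")
    return float(stats.chi2.sf(chi2_value, nu))


def select_binning(radial_positions_by_time: Sequence[tuple[float, np.ndarray]],
                   geometry: ShellGeometry,
                   growth: GrowthLaw,
                   candidate_widths: Sequence[float],
                   candidate_exclusions: Sequence[float] = (4.0,),
                   delta_r: float = 3.0,
                   cmax: float = 4.12e-3,
                   grid: np.ndarray | None = None,
                   n_nodes: int = 200) -> BinSpec:
    """Choose the bin width/exclusion whose pooled fit has P_chi closest to 0.5.

    Runs the nonlinear fit for every candidate (width, exclusion) pair on the
    given per-time radial positions and returns the argmin of
    |median-over-time P_chi - 0.5|.
    """
    from .profile import concentration_profile
    cands = [(w, e) for w in candidate_widths for e in candidate_exclusions]
    if not cands:
        raise ValueError("need at least one candidate")
    if len(cands) == 1:
        return BinSpec(bin_width=cands[0][0], apical_exclusion=cands[0][1],
                       basal_exclusion=cands[0][1])
    best = None
    for w, e in cands:
        spec = BinSpec(bin_width=w, apical_exclusion=e, basal_exclusion=e)
        try:
            profiles = [concentration_profile(r, geometry, spec, delta_r, t=t)
                        for t, r in radial_positions_by_time]
            fit = scan_D(profiles, geometry, growth, model="nonlinear",
                         cmax=cmax, grid=grid, n_nodes=n_nodes)
            # per-time-point χ² at the pooled optimum
            p0 = profiles[0]
            params0 = build_solution(geometry, growth, fit.D_star,
                                     p0.xi_centers, p0.dxi, p0.c)
            ic = lambda x: np.clip(evaluate_linear(x, 0.0, params0), 0.0, None)
            t_grid = np.unique(np.concatenate(
                [[0.0], [p.t for p in profiles]]))
            sol = solve_nonlinear(ic, fit.D_star, cmax, geometry, growth,
                                  t_grid, n_nodes=n_nodes)
            ps = []
            for p in profiles:
                nu_p = int(p.fit_mask.sum() - 1)
                if nu_p < 1:
                    raise ValueError("degenerate binning")
                xi = p.xi_centers[p.fit_mask]
                v, _ = chi2(p, sol.interp(xi, p.t),
                            model_gradient(sol, xi, p.t))
                ps.append(p_chi(v, nu_p))
            score = abs(float(np.median(ps)) - 0.5)
        except (ValueError, RuntimeError):
            continue
        if best is None or score < best[0]:
            best = (score, spec)
    if best is None:
        raise ValueError("all candidate binnings degenerate")
    return best[1]


def welch_test(D1: float, s1: float, n1: int,
               D2: float, s2: float, n2: int) -> tuple[float, float]:
    """Welch's unequal-variances two-sample t-test from summary statistics.

    Returns (t, two-sided p) with Welch-Satterthwaite degrees of freedom.
    """
    if s1 <= 0 or s2 <= 0:
        raise ValueError("standard deviations must be positive")
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    res = stats.ttest_ind_from_stats(D1, s1, n1, D2, s2, n2, equal_var=False)
    return float(res.statistic), float(res.pvalue)
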