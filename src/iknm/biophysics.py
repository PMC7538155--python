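"""Biophysical interpretation of the effective nuclear diffusion constant.

Converts the tissue-scale diffusivity D (µm²/min) extracted from
concentration-profile fits into physical statements about what drives the
nuclei: comparison with free thermal (Stokes-Einstein) diffusion, drag
inside a tight-fitting membrane tube, the integrated strength Γ of the
stochastic driving force and the force scale it implies, plus the
close-packing concentration that parameterizes the crowding model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "KB",
    "PhysicalEnvironment",
    "stokes_drag",
    "stokes_einstein",
    "close_packed_cmax",
    "packing_fraction",
    "tube_drag",
    "gamma_strength",
    "force_scale",
    "D_um2_min_to_m2_s",
    "D_m2_s_to_um2_min",
]

#: Boltzmann constant, J/K
KB = 1.38e-23

#: close packing fraction of equal spheres (also aligned ellipsoids), pi/(3 sqrt 2)
SPHERE_PACKING_FRACTION = math.pi / (3.0 * math.sqrt(2.0))


def D_um2_min_to_m2_s(D: float) -> float:
    """Convert a diffusivity from µm²/min to m²/s."""
    return D * 1e-12 / 60.0


def D_m2_s_to_um2_min(D: float) -> float:
    """Convert a diffusivity from m²/s to µm²/min."""
    return D * 1e12 * 60.0


@dataclass(frozen=True)
class PhysicalEnvironment:
    """Physical constants of the intracellular environment.

    Defaults: water at 25 °C, nuclear radius matching the fitted close-packing
    concentration, fluid-membrane bending modulus kappa ~ 20 kBT and a
    molecular length of 1 nm setting the tension scale gamma = kBT/l².
    """

    T: float = 298.15          # K
    eta: float = 9e-4          # Pa s
    R: float = 3.5             # µm, nuclear radius
    kappa_over_kBT: float = 20.0
    ell: float = 1e-9          # m, molecular length for the tension estimate

    def __post_init__(self) -> None:
        for name in ("T", "eta", "R", "kappa_over_kBT", "ell"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def gamma(self) -> float:
        """Surface tension kBT / ell², J/m²."""
        return KB * self.T / self.ell**2

    @property
    def gammaR2_over_kBT(self) -> float:
        """Dimensionless tension ratio gamma R² / kBT = (R/ell)²."""
        return (self.R * 1e-6 / self.ell) ** 2


def stokes_drag(eta: float, R: float) -> float:
    """Stokes drag coefficient zeta0 = 6 pi eta R for a sphere, kg/s.

    ``eta`` in Pa·s, ``R`` in µm.
    """
    if eta < 0 or R < 0:
        raise ValueError("eta and R must be non-negative")
    return 6.0 * math.pi * eta * R * 1e-6


def stokes_einstein(T: float, zeta: float) -> float:
    """Thermal diffusivity D = kB T / zeta, returned in µm²/min."""
    if T <= 0 or zeta <= 0:
        raise ValueError("T and zeta must be positive")
    return D_m2_s_to_um2_min(KB * T / zeta)


def close_packed_cmax(R: float) -> float:
    """Maximum nuclear concentration from close packing, µm⁻³.

    Spheres (and aligned ellipsoids) pack at fraction pi/(3 sqrt 2) ≈ 0.74 of
    space; dividing by the nuclear volume (4/3) pi R³ gives the maximal
    number concentration.
    """
    if R <= 0:
        raise ValueError("R must be positive")
    return SPHERE_PACKING_FRACTION / (4.0 / 3.0 * math.pi * R**3)


def packing_fraction() -> float:
    """Close-packing fraction of equal spheres, pi/(3 sqrt 2)."""
    return SPHERE_PACKING_FRACTION


def tube_drag(zeta0: float, kappa_over_kBT: float, gammaR2_over_kBT: float) -> float:
    """Drag on a sphere inside a fluctuating tight membrane tube, kg/s.

    zeta_tube = (3/2) zeta0 [ (kappa/kBT) (gamma R²/kBT) ]^{2/3}; valid in the
    large-tension regime of a tight-fitting tube, where thermal membrane
    fluctuations set the lubrication gap.
    """
    if zeta0 <= 0 or kappa_over_kBT < 0 or gammaR2_over_kBT < 0:
        raise ValueError("zeta0 must be positive, ratios non-negative")
    return 1.5 * zeta0 * (kappa_over_kBT * gammaR2_over_kBT) ** (2.0 / 3.0)


def gamma_strength(zeta: float, D: float) -> float:
    """Integrated autocorrelation of the stochastic force, Γ = 6 ζ² D (N²·s).

    ``zeta`` in kg/s, ``D`` in µm²/min (converted internally to m²/s).
    The relation follows from <r(t)²> = Γ t / ζ² = 6 D t for dilute 3-D
    Brownian motion.
    """
    if zeta < 0 or D < 0:
        raise ValueError("zeta and D must be non-negative")
    return 6.0 * zeta**2 * D_um2_min_to_m2_s(D)


def force_scale(Gamma: float, tau_c: float) -> float:
    """Characteristic force sqrt(Γ / tau_c), N.

    For a stochastic force with integrated autocorrelation Γ and correlation
    time tau_c (s), the root-mean-square force scale is sqrt(Γ/tau_c).
    """
    if Gamma < 0 or tau_c <= 0:
        raise ValueError("Gamma must be non-negative, tau_c positive")
    return math.sqrt(Gamma / tau_c)


def report(D: float = 0.09, R: float = 3.5, env: PhysicalEnvironment | None = None,
           zeta_multipliers: tuple[float, float] = (2e5, 1e6),
           tau_c_range_s: tuple[float, float] = (0.01, 1.0)) -> dict:
    """All derived biophysical quantities for a fitted D (µm²/min).

    ``zeta_multipliers`` bracket the plausible intracellular drag relative to
    the Stokes reference (membrane-tube confinement puts it at ~1e5-1e6 zeta0);
    ``tau_c_range_s`` brackets cytoskeletal force correlation times.
    """
    if env is None:
        env = PhysicalEnvironment(R=R)
    zeta0 = stokes_drag(env.eta, env.R)
    D_th = stokes_einstein(env.T, zeta0)
    zt = tube_drag(zeta0, env.kappa_over_kBT, env.gammaR2_over_kBT)
    Gamma_lo = gamma_strength(zeta_multipliers[0] * zeta0, D)
    Gamma_hi = gamma_strength(zeta_multipliers[1] * zeta0, D)
    return {
        "D_um2_min": D,
        "zeta0_kg_s": zeta0,
        "D_thermal_um2_min": D_th,
        "thermal_over_fitted": D_th / D,
        "cmax_um3": close_packed_cmax(env.R),
        "packing_fraction": packing_fraction(),
        "zeta_tube_over_zeta0": zt / zeta0,
        "D_tube_over_D_thermal": zeta0 / zt,
        "Gamma_N2s_low": Gamma_lo,
        "Gamma_N2s_high": Gamma_hi,
        "force_nN_low": force_scale(Gamma_lo, tau_c_range_s[1]) * 1e9,
        "force_nN_high": force_scale(Gamma_hi, tau_c_range_s[0]) * 1e9,
    }
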