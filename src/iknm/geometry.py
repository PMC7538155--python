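"""Shell geometry and population growth law for the retinal neuroepithelium.

The retina is idealized as a sector of a spherical shell centred on the lens:
the basal surface sits at radius ``b``, the apical (dividing) surface at
radius ``a`` and the tracked region subtends a solid angle ``Omega``.  All
geometric quantities used downstream (bin volumes, apical influx area) follow
exactly from ``(a, b, Omega)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = ["ShellGeometry", "GrowthLaw", "shell_volumes"]


@dataclass(frozen=True)
class ShellGeometry:
    """Spherical-shell sector in which nuclei move.

    Parameters
    ----------
    a : float
        Apical radius (distance lens centre -> apical surface), µm.
    b : float
        Basal radius, µm. ``0 < b < a``.
    Omega : float
        Solid angle of the observed sector, steradian.  A half shell
        (the default experimental idealization) has ``Omega = 2*pi``.
    """

    a: float
    b: float
    Omega: float = 2.0 * math.pi

    def __post_init__(self) -> None:
        if not 0.0 < self.b < self.a:
            raise ValueError(f"require 0 < b < a, got a={self.a}, b={self.b}")
        if not 0.0 < self.Omega <= 4.0 * math.pi + 1e-12:
            raise ValueError(f"solid angle must lie in (0, 4*pi], got {self.Omega}")

    @property
    def rho(self) -> float:
        """Dimensionless basal radius b/a."""
        return self.b / self.a

    @property
    def S(self) -> float:
        """Apical influx area, µm² (``Omega * a**2``)."""
        return self.Omega * self.a**2

    @property
    def Vtotal(self) -> float:
        """Sector volume, µm³ (``Omega * (a^3 - b^3) / 3``)."""
        return self.Omega * (self.a**3 - self.b**3) / 3.0

    @property
    def thickness(self) -> float:
        """Tissue thickness a - b, µm."""
        return self.a - self.b

    @classmethod
    def from_volume(cls, a: float, b: float, Vtotal: float) -> "ShellGeometry":
        """Build geometry from a measured sector volume: Omega = 3 V/(a³-b³)."""
        return cls(a=a, b=b, Omega=3.0 * Vtotal / (a**3 - b**3))


@dataclass(frozen=True)
class GrowthLaw:
    """Exponential nuclear-number growth N(t) = N0 * exp(t / tau).

    ``tau = TP / ln 2`` with ``TP`` the mean cell-cycle length, so the
    population doubles every ``TP`` minutes.  ``TP = inf`` encodes the
    divisions-absent (drug block) case.
    """

    N0: float
    TP: float  # min

    def __post_init__(self) -> None:
        if self.N0 < 1:
            raise ValueError(f"N0 must be >= 1, got {self.N0}")
        if not self.TP > 0:
            raise ValueError(f"TP must be positive, got {self.TP}")

    @property
    def tau(self) -> float:
        """Exponential time constant TP / ln2, min."""
        return self.TP / math.log(2.0)

    def N(self, t) -> np.ndarray:
        """Expected nucleus count at time(s) ``t`` (min)."""
        t = np.asarray(t, dtype=float)
        if math.isinf(self.TP):
            return np.broadcast_to(float(self.N0), t.shape).copy()
        return self.N0 * np.exp(t / self.tau)

    def influx_rate(self, t) -> np.ndarray:
        """dN/dt = N0/tau * exp(t/tau), nuclei per minute."""
        t = np.asarray(t, dtype=float)
        if math.isinf(self.TP):
            return np.zeros_like(t)
        return self.N0 / self.tau * np.exp(t / self.tau)

    @property
    def divisions_absent(self) -> bool:
        return math.isinf(self.TP)


def shell_volumes(geometry: ShellGeometry, edges: np.ndarray) -> np.ndarray:
    """Volumes of radial bins between successive ``edges`` (µm).

    ``V_bin = Omega/3 * (r_outer^3 - r_inner^3)`` — the exact spherical-sector
    formula, so equal-width bins telescope to the sector volume of the
    binned range.

    Parameters
    ----------
    geometry : ShellGeometry
    edges : array of bin edges in µm, strictly increasing, within [b, a]
      (a small tolerance absorbs floating-point edge placement).
    """
    edges = np.asarray(edges, dtype=float)
    if edges.ndim != 1 or edges.size < 2:
        raise ValueError("need at least two bin edges")
    if np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must be strictly increasing")
    tol = 1e-9 * geometry.a
    if edges[0] < geometry.b - tol or edges[-1] > geometry.a + tol:
        raise ValueError(
            f"edges [{edges[0]}, {edges[-1]}] outside shell [{geometry.b}, {geometry.a}]"
        )
    return geometry.Omega / 3.0 * np.diff(edges**3)
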