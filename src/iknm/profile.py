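"""Radial concentration profiles with the bin-count uncertainty model.

Each measured radial position carries a uniform error box of half-width
delta_r; the probability that nucleus n falls in a bin is the fractional
overlap of its error box with the bin, giving per-bin expected counts
E(N) = sum_n p_n and variances Var(N) = sum_n p_n (1 - p_n).  Dividing by the
exact spherical bin volumes yields the concentration and its y-error; the
x-error of a bin centre is taken as sqrt(bin width) (in µm, with a 1 µm
reference scale making the square root dimensionally explicit).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .geometry import GrowthLaw, ShellGeometry, shell_volumes

__all__ = [
    "BinSpec",
    "ConcentrationProfile",
    "bin_positions",
    "concentration_profile",
    "fit_growth",
    "mean_apical_distance",
]


@dataclass(frozen=True)
class BinSpec:
    """Radial binning: bin width plus apical/basal exclusion zones (all µm).

    Bins are laid from the basal edge upward; a final partial bin at the
    apical side keeps its true (smaller) volume.  Exclusion zones mark bins
    whose centres fall within ``apical_exclusion`` of a (or
    ``basal_exclusion`` of b) as not-for-fitting: nuclear centres cannot
    approach a surface closer than one nuclear radius, so counts there are
    measurement artefacts.
    """

    bin_width: float = 3.0
    apical_exclusion: float = 4.0
    basal_exclusion: float = 4.0

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        if self.apical_exclusion < 0 or self.basal_exclusion < 0:
            raise ValueError("exclusions must be non-negative")

    def edges(self, geometry: ShellGeometry) -> np.ndarray:
        """Bin edges in µm from b to a (last bin possibly partial)."""
        e = np.arange(geometry.b, geometry.a, self.bin_width, dtype=float)
        return np.append(e, geometry.a)


def bin_positions(radial_positions: np.ndarray, delta_r: float,
                  edges: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Expected counts and variances per bin under the uniform error-box model.

    p_{n,bin} = |overlap([r_n - dr, r_n + dr], bin)| / (2 dr); for dr = 0 a
    point mass is assigned to the containing bin.  Positions whose boxes fall
    entirely outside the binned range simply contribute nothing.
    """
    r = np.asarray(radial_positions, dtype=float)
    edges = np.asarray(edges, dtype=float)
    if np.any(np.diff(edges) <= 0):
        raise ValueError("edges must be strictly increasing")
    if delta_r < 0:
        raise ValueError("delta_r must be non-negative")
    nbin = edges.size - 1
    if delta_r == 0.0:
        idx = np.searchsorted(edges, r, side="right") - 1
        # right edge of the last bin is inclusive
        idx[np.isclose(r, edges[-1])] = nbin - 1
        ok = (idx >= 0) & (idx < nbin)
        E = np.bincount(idx[ok], minlength=nbin).astype(float)
        return E, np.zeros(nbin)
    lo = r[:, None] - delta_r
    hi = r[:, None] + delta_r
    overlap = (np.minimum(hi, edges[None, 1:]) - np.maximum(lo, edges[None, :-1]))
    p = np.clip(overlap, 0.0, None) / (2.0 * delta_r)
    E = p.sum(axis=0)
    Var = (p * (1.0 - p)).sum(axis=0)
    return E, Var


@dataclass(frozen=True)
class ConcentrationProfile:
    """Binned radial concentration at one time point, in xi = r/a units."""

    t: float                    # min
    xi_centers: np.ndarray
    dxi: np.ndarray
    expected_counts: np.ndarray
    var_counts: np.ndarray
    V_bin: np.ndarray           # µm³
    c: np.ndarray               # µm⁻³
    sigma_y: np.ndarray         # µm⁻³
    sigma_x: np.ndarray         # xi-units
    fit_mask: np.ndarray        # bins outside exclusion zones

    @property
    def n_bins(self) -> int:
        return self.xi_centers.size

    def fitting_view(self) -> "ConcentrationProfile":
        """Restriction to the bins used for fitting (exclusions dropped)."""
        m = self.fit_mask
        return ConcentrationProfile(
            t=self.t, xi_centers=self.xi_centers[m], dxi=self.dxi[m],
            expected_counts=self.expected_counts[m], var_counts=self.var_counts[m],
            V_bin=self.V_bin[m], c=self.c[m], sigma_y=self.sigma_y[m],
            sigma_x=self.sigma_x[m], fit_mask=np.ones(m.sum(), dtype=bool))


def concentration_profile(radial_positions: np.ndarray,
                          geometry: ShellGeometry,
                          binspec: BinSpec = BinSpec(),
                          delta_r: float = 3.0,
                          t: float = 0.0) -> ConcentrationProfile:
    """Concentration profile from radial nuclear positions (µm) at one time.

    Composition of the error-box binning and the exact shell volumes on
    xi-rescaled coordinates.  ``sigma_x`` is sqrt(bin width / 1 µm) µm,
    converted to xi-units by dividing by a.
    """
    r = np.asarray(radial_positions, dtype=float)
    if r.size == 0:
        raise ValueError("no nuclei at this time point")
    edges = binspec.edges(geometry)
    E, Var = bin_positions(r, delta_r, edges)
    V = shell_volumes(geometry, edges)
    a = geometry.a
    centers = 0.5 * (edges[:-1] + edges[1:])
    widths = np.diff(edges)
    c = E / V
    sigma_y = np.sqrt(Var) / V
    sigma_x = np.sqrt(widths) / a   # sqrt(width·1µm) in µm, then /a -> xi
    fit_mask = ((centers >= geometry.b + binspec.basal_exclusion)
                & (centers <= geometry.a - binspec.apical_exclusion))
    return ConcentrationProfile(
        t=float(t), xi_centers=centers / a, dxi=widths / a,
        expected_counts=E, var_counts=Var, V_bin=V, c=c,
        sigma_y=sigma_y, sigma_x=sigma_x, fit_mask=fit_mask)


def fit_growth(counts, N0: float | None = None) -> GrowthLaw:
    """Least-squares exponential growth fit in log-lin space.

    ``counts`` is a sequence of (t_min, N) pairs.  ln N = ln N0 + (ln2/TP) t;
    when ``N0`` is given (the known initial tracked count) only the slope is
    fitted.  A slope <= 0 (no growth) returns the divisions-absent law
    ``TP = inf``.
    """
    arr = np.asarray(counts, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise ValueError("need >= 3 (t, N) pairs")
    t, N = arr[:, 0], arr[:, 1]
    if np.any(N <= 0):
        raise ValueError("all counts must be positive")
    y = np.log(N)
    if N0 is not None:
        slope = np.sum(t * (y - math.log(N0))) / np.sum(t * t)
        n0 = float(N0)
    else:
        slope, intercept = np.polyfit(t, y, 1)
        n0 = math.exp(intercept)
    if slope <= 1e-12:
        return GrowthLaw(N0=n0, TP=math.inf)
    return GrowthLaw(N0=n0, TP=math.log(2.0) / slope)


def mean_apical_distance(profile: ConcentrationProfile, a: float) -> float:
    """E(N)-weighted mean distance of nuclei from the apical surface, µm."""
    w = profile.expected_counts
    if w.sum() <= 0:
        raise ValueError("profile carries no mass")
    dist = a * (1.0 - profile.xi_centers)
    return float(np.sum(w * dist) / w.sum())
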