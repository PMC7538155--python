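"""Apicobasal coordinates and descriptive track statistics.

Converts Cartesian nuclear tracks into the radial (apicobasal) coordinate
r = a - l_n, with l_n the distance to the apical surface, and computes the
descriptive statistics used to characterize IKNM: signed speeds over the
normalized cell cycle, speed correlations with cylindrical neighborhoods,
and the experimental mean-squared-displacement curve aligned to birth.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .geometry import ShellGeometry
from .synthetic import NucleusTrack

__all__ = [
    "ApicalSurfaceFit",
    "RadialTrack",
    "MSDCurve",
    "fit_apical_surface",
    "to_radial",
    "cycle_normalized_kinematics",
    "neighbor_speed_correlation",
    "experimental_msd",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ApicalSurfaceFit:
    """Quadratic contours of the apical surface in the XY and YZ planes."""

    coeffs_xy: np.ndarray   # y ≈ c2 x² + c1 x + c0
    coeffs_yz: np.ndarray   # y ≈ c2 z² + c1 z + c0
    rmse: float             # µm, pooled residual

    @property
    def curvature_xy(self) -> float:
        """Curvature of the XY contour at its apex, 1/µm (≈ |2 c2|)."""
        return abs(2.0 * self.coeffs_xy[0])


def _quad_fit(u: np.ndarray, v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    if np.ptp(u) < 1e-9 * (1 + np.abs(u).max()):
        raise ValueError("degenerate contour: abscissae are collinear")
    coeffs = np.polyfit(u, v, 2)
    resid = v - np.polyval(coeffs, u)
    return coeffs, resid


def fit_apical_surface(contour_points: np.ndarray) -> ApicalSurfaceFit:
    """Least-squares quadratics through apical contour points (n, 3).

    Fits y as a quadratic of x (XY plane) and of z (YZ plane).  Deterministic;
    requires at least 6 points with spread abscissae.
    """
    pts = np.asarray(contour_points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 6:
        raise ValueError("need >= 6 contour points of shape (n, 3)")
    cxy, r1 = _quad_fit(pts[:, 0], pts[:, 1])
    cyz, r2 = _quad_fit(pts[:, 2], pts[:, 1])
    rmse = float(np.sqrt(np.mean(np.concatenate([r1, r2]) ** 2)))
    return ApicalSurfaceFit(coeffs_xy=cxy, coeffs_yz=cyz, rmse=rmse)


@dataclass
class RadialTrack:
    """A track reduced to its apicobasal coordinate r(t) = a - l_n(t)."""

    id: int
    parent_id: int | None
    birth_t: float
    t: np.ndarray
    r: np.ndarray              # µm
    cycle_complete: bool
    flagged: np.ndarray        # samples outside [b - dr, a + dr]

    def __len__(self) -> int:
        return self.t.size


def to_radial(tracks: Sequence[NucleusTrack], geometry: ShellGeometry,
              delta_r: float = 3.0) -> list[RadialTrack]:
    """Convert Cartesian tracks to radial tracks about the shell centre.

    The synthetic shell is centred at the origin, so r is simply the
    Euclidean norm; samples outside [b - delta_r, a + delta_r] are flagged
    (never clipped).  ``cycle_complete`` marks tracks observed from birth to
    division (fate recorded by the simulator/reader).
    """
    out = []
    for tr in tracks:
        r = tr.r
        flagged = (r < geometry.b - delta_r) | (r > geometry.a + delta_r)
        out.append(RadialTrack(
            id=tr.id, parent_id=tr.parent_id, birth_t=tr.birth_t,
            t=tr.t.copy(), r=r, cycle_complete=(tr.fate == "divided"),
            flagged=flagged))
    return out


def _signed_speeds(r: np.ndarray, dt: float) -> np.ndarray:
    """Signed apicobasal speed, basalward positive (= -dr/dt).

    Centred differences in the interior, one-sided at the ends.
    """
    v = np.empty_like(r)
    v[1:-1] = (r[2:] - r[:-2]) / (2 * dt)
    v[0] = (r[1] - r[0]) / dt
    v[-1] = (r[-1] - r[-2]) / dt
    return -v


def cycle_normalized_kinematics(radial_tracks: Sequence[RadialTrack],
                                frame_dt: float = 2.0,
                                a: float | None = None) -> list[dict]:
    """Per-track speed and apical distance over normalized cycle time.

    Only tracks with a complete cycle qualify; tracks shorter than 3 frames
    are excluded (their count is logged).  Returns one dict per track with
    keys ``id``, ``tau`` (normalized time in [0, 1]), ``speed`` (µm/min,
    basalward positive) and ``apical_distance`` (µm, requires ``a``).
    """
    out = []
    skipped = 0
    for tr in radial_tracks:
        if not tr.cycle_complete:
            continue
        if len(tr) < 3:
            skipped += 1
            continue
        tau = (tr.t - tr.t[0]) / (tr.t[-1] - tr.t[0])
        rec = {"id": tr.id, "tau": tau, "speed": _signed_speeds(tr.r, frame_dt)}
        if a is not None:
            rec["apical_distance"] = a - tr.r
        out.append(rec)
    if skipped:
        log.info("cycle_normalized_kinematics: excluded %d short tracks", skipped)
    return out


def _pearson_ci(r: float, n: int) -> tuple[float, float]:
    """95% CI for a Pearson correlation via the Fisher z-transform."""
    if n < 4 or abs(r) >= 1.0:
        return (float("nan"), float("nan"))
    z = math.atanh(r)
    se = 1.0 / math.sqrt(n - 3)
    return (math.tanh(z - 1.96 * se), math.tanh(z + 1.96 * se))


def neighbor_speed_correlation(tracks: Sequence[NucleusTrack],
                               geometry: ShellGeometry,
                               long_axis: float = 5.3,
                               short_axis: float = 3.5,
                               lag: int = 0,
                               frame_dt: float = 2.0,
                               min_pairs: int = 10) -> dict:
    """Correlation of a nucleus' speed with the mean speed of its neighbors.

    Neighbors at a time point are nuclei whose centres fall inside a cylinder
    aligned with the local apicobasal (radial) direction: height twice the
    long axis, base diameter twice the short axis.  Speeds are radial and
    signed (basalward positive); the neighbor speed may be taken ``lag``
    frames before (+1: neighbor leads) or after the focal speed.

    Pairs (focal speed, mean neighbor speed) are accumulated per (nucleus,
    time point) and split into eight categories: neighbor apical/basal of the
    focal nucleus x neighbor moving apicalward/basalward x co-/counter-moving
    relative to the focal nucleus.  Categories with fewer than ``min_pairs``
    pairs are reported as None.  Returns ``{"pooled": (r, n, ci), <category>:
    ...}``.
    """
    if abs(lag) > 1:
        raise ValueError("lag must be -1, 0 or +1")
    if len(tracks) < 2:
        raise ValueError("need at least two tracks")
    # index samples by time
    frame_of: dict[float, list[tuple[int, np.ndarray, float]]] = {}
    speeds = {}
    for k, tr in enumerate(tracks):
        if len(tr) < 3:
            continue
        v = _signed_speeds(tr.r, frame_dt)
        speeds[k] = v
        for j, t in enumerate(tr.t):
            frame_of.setdefault(round(float(t), 6), []).append((k, tr.xyz[j], j))
    pairs: dict[str, list[tuple[float, float]]] = {}

    def add(cat: str, f: float, m: float) -> None:
        pairs.setdefault(cat, []).append((f, m))

    for t, entries in frame_of.items():
        if len(entries) < 2:
            continue
        pos = np.array([e[1] for e in entries])
        rads = np.linalg.norm(pos, axis=1)
        units = pos / rads[:, None]
        for i, (ki, pi, ji) in enumerate(entries):
            vi = speeds[ki][ji]
            # cylinder test in the focal frame
            d = pos - pi
            axial = d @ units[i]
            lat2 = np.einsum("ij,ij->i", d, d) - axial**2
            inside = ((np.abs(axial) <= long_axis)
                      & (lat2 <= short_axis**2))
            inside[i] = False
            neigh_speeds = []
            neigh_axial = []
            for jidx in np.flatnonzero(inside):
                kn, _, jn = entries[jidx]
                jlag = jn + lag
                if 0 <= jlag < speeds[kn].size:
                    neigh_speeds.append(speeds[kn][jlag])
                    neigh_axial.append(axial[jidx])
            if not neigh_speeds:
                continue
            vm = float(np.mean(neigh_speeds))
            add("pooled", vi, vm)
            for vs, ax in zip(neigh_speeds, neigh_axial):
                c1 = "apical" if ax > 0 else "basal"
                c2 = "basalward" if vs > 0 else "apicalward"
                c3 = "same" if vs * vi >= 0 else "opposite"
                add(f"{c1}/{c2}/{c3}", vi, vs)
    result = {}
    for cat, pl in pairs.items():
        arr = np.array(pl)
        n = arr.shape[0]
        if n < min_pairs or np.std(arr[:, 0]) == 0 or np.std(arr[:, 1]) == 0:
            if np.allclose(arr[:, 0], arr[:, 1]) and n >= 2:
                result[cat] = {"r": 1.0, "n": n, "ci": (1.0, 1.0)}
            else:
                result[cat] = None
            continue
        r = float(np.corrcoef(arr[:, 0], arr[:, 1])[0, 1])
        result[cat] = {"r": r, "n": n, "ci": _pearson_ci(r, n)}
    return result


@dataclass(frozen=True)
class MSDCurve:
    """Mean squared radial displacement vs cell-cycle time lag."""

    lags: np.ndarray            # min
    msd: np.ndarray             # µm²
    n_contributing: np.ndarray  # tracks per lag


def experimental_msd(radial_tracks: Sequence[RadialTrack],
                     n_select: int = 40,
                     min_len: int = 75,
                     window: float = 200.0,
                     frame_dt: float = 2.0,
                     msd_dims: int = 1) -> MSDCurve:
    """MSD of the earliest-born cohort, aligned to birth.

    Selects the ``n_select`` earliest-born tracks having at least ``min_len``
    frames entirely within the first ``window`` minutes, subtracts each
    nucleus' birth time, and averages the squared displacement from the birth
    position per cell-cycle lag.  ``msd_dims=1`` (default) uses the radial
    (apicobasal) component — the tracked biological signal; ``msd_dims=3``
    uses the full 3-D displacement and requires tracks carrying ``xyz``.
    """
    if msd_dims not in (1, 3):
        raise ValueError("msd_dims must be 1 or 3")
    qualifying = []
    for tr in radial_tracks:
        span = min(len(tr), int(math.floor((window - tr.t[0]) / frame_dt)) + 1)
        if span >= min_len and tr.t[0] <= window:
            qualifying.append((tr.birth_t, tr, span))
    if len(qualifying) < n_select:
        raise ValueError(
            f"only {len(qualifying)} qualifying tracks, need {n_select}")
    qualifying.sort(key=lambda q: (q[0], q[1].id))
    chosen = qualifying[:n_select]
    max_lag = max(q[2] for q in chosen)
    sums = np.zeros(max_lag)
    counts = np.zeros(max_lag, dtype=int)
    for _, tr, span in chosen:
        if msd_dims == 1:
            disp2 = (tr.r[:span] - tr.r[0]) ** 2
        else:
            xyz = tr.xyz  # requires Cartesian tracks
            disp2 = np.sum((xyz[:span] - xyz[0]) ** 2, axis=1)
        sums[:span] += disp2
        counts[:span] += 1
    msd = np.divide(sums, counts, out=np.zeros_like(sums), where=counts > 0)
    lags = np.arange(max_lag) * frame_dt
    return MSDCurve(lags=lags, msd=msd, n_contributing=counts)
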