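"""Seeded synthetic nuclear-track datasets with the statistics of IKNM.

Emulates what light-sheet/two-photon tracking of the zebrafish retinal
neuroepithelium produces: nuclei confined to a half-spherical shell, dividing
exclusively at the apical surface with exponential population growth,
stochastic radial G1/S motion (optionally coupled to the live nuclear
concentration, the crowding variant), a brief deterministic apical G2 run,
a drug-block mode with no divisions, and uniform radial measurement noise.

Tracks are exported as plain CSV with lineage, so the whole analysis chain
(coordinate conversion, profiling, model fitting) runs on data whose ground
truth is known.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .geometry import GrowthLaw, ShellGeometry

__all__ = [
    "NucleusTrack",
    "SimulationConfig",
    "simulate_population",
    "apply_measurement_noise",
    "write_tracks",
    "read_tracks",
]

VARIANTS = ("low_c", "gamma_c", "external_force")


@dataclass
class NucleusTrack:
    """One nucleus: timestamped 3-D positions plus lineage."""

    id: int
    parent_id: int | None
    birth_t: float                 # min
    t: np.ndarray                  # min, uniform spacing
    xyz: np.ndarray                # (n, 3) µm
    fate: str = "censored"         # "divided" | "censored"

    @property
    def r(self) -> np.ndarray:
        """Radial distance from the shell centre, µm."""
        return np.linalg.norm(self.xyz, axis=1)

    def __len__(self) -> int:
        return self.t.size


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for a synthetic population.

    Defaults are the conditions of the imaged tissue: 2 min frame cadence,
    nuclear radius 3.5 µm, G2 occupying ~8% of the cycle, uniform ±3 µm
    radial measurement noise, and a geometry with 55 µm tissue thickness
    (the apical radius itself is a documented stand-in — it is not printed
    for the experimental retina and only enters through ratios).
    """

    geometry: ShellGeometry = field(default_factory=lambda: ShellGeometry(a=100.0, b=45.0))
    growth: GrowthLaw = field(default_factory=lambda: GrowthLaw(N0=100, TP=300.0))
    frame_dt: float = 2.0          # min
    duration: float = 300.0        # min
    D: float = 0.09                # µm²/min
    cmax: float = 4.12e-3          # µm⁻³
    variant: str = "low_c"
    g2_fraction: float = 0.08
    v_apical: float | None = None  # µm/min; None -> run completes from basal-most
    delta_r_noise: float = 3.0     # µm
    divisions_enabled: bool = True
    seed: int = 0
    nuclear_radius: float = 3.5    # µm; reflecting walls at b+R, a-R
    cycle_cv: float = 0.15
    initial_condition: str = "uniform"   # "uniform" | "apical"
    population_cap: int = 50_000

    def __post_init__(self) -> None:
        if self.frame_dt <= 0:
            raise ValueError("frame_dt must be positive")
        if not 0 <= self.g2_fraction < 1:
            raise ValueError("g2_fraction must lie in [0, 1)")
        if self.delta_r_noise < 0:
            raise ValueError("delta_r_noise must be non-negative")
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")
        if self.initial_condition not in ("uniform", "apical"):
            raise ValueError("initial_condition must be 'uniform' or 'apical'")

    @property
    def r_min(self) -> float:
        return self.geometry.b + self.nuclear_radius

    @property
    def r_max(self) -> float:
        return self.geometry.a - self.nuclear_radius

    @property
    def apical_speed(self) -> float:
        """G2 run speed: complete the basal-most -> apical run inside G2."""
        if self.v_apical is not None:
            return self.v_apical
        g2_time = max(self.g2_fraction * self.growth.TP, self.frame_dt)
        return (self.r_max - self.r_min) / g2_time


def _reflect(r: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Reflect positions into [lo, hi] (handles multiple bounces)."""
    span = hi - lo
    y = np.mod(r - lo, 2 * span)
    y = np.where(y > span, 2 * span - y, y)
    return lo + y


def _live_concentration(r: np.ndarray, cfg: SimulationConfig,
                        bin_width: float = 3.0) -> np.ndarray:
    """Mean-field concentration estimate at each nucleus position.

    Bins the current radial positions into spherical shells over the full
    accessible thickness and linearly interpolates the per-shell density back
    to the nuclei.  This is the self-consistent coupling that makes the
    crowding variants interacting.
    """
    g = cfg.geometry
    edges = np.linspace(g.b, g.a, max(int(round((g.a - g.b) / bin_width)), 3) + 1)
    counts, _ = np.histogram(r, bins=edges)
    V = g.Omega / 3.0 * np.diff(edges**3)
    c = counts / V
    centers = 0.5 * (edges[:-1] + edges[1:])
    return np.interp(r, centers, c)


def _live_concentration_gradient(r: np.ndarray, cfg: SimulationConfig,
                                 bin_width: float = 3.0) -> tuple[np.ndarray, np.ndarray]:
    """(c, dc/dr) at each nucleus position from the live binned estimate."""
    g = cfg.geometry
    edges = np.linspace(g.b, g.a, max(int(round((g.a - g.b) / bin_width)), 3) + 1)
    counts, _ = np.histogram(r, bins=edges)
    V = g.Omega / 3.0 * np.diff(edges**3)
    c = counts / V
    centers = 0.5 * (edges[:-1] + edges[1:])
    grad = np.gradient(c, centers)
    return np.interp(r, centers, c), np.interp(r, centers, grad)


class _Pop:
    """Mutable state of the growing population during simulation."""

    __slots__ = ("r", "theta", "phi", "birth", "cycle", "ids", "parents",
                 "traj", "next_id")

    def __init__(self) -> None:
        self.r = np.empty(0)
        self.theta = np.empty(0)
        self.phi = np.empty(0)
        self.birth = np.empty(0)
        self.cycle = np.empty(0)
        self.ids = np.empty(0, dtype=int)
        self.parents: dict[int, int | None] = {}
        self.traj: dict[int, list[tuple[float, float, float, float]]] = {}
        self.next_id = 0


def _draw_cycles(rng: np.random.Generator, n: int, cfg: SimulationConfig) -> np.ndarray:
    """Per-cell cycle lengths: truncated normal, floored at the G2 duration."""
    TP = cfg.growth.TP
    if math.isinf(TP):
        return np.full(n, math.inf)
    floor = max(cfg.g2_fraction * TP, 2 * cfg.frame_dt)
    c = rng.normal(TP, cfg.cycle_cv * TP, size=n)
    c = np.clip(c, floor, None)
    # frame-align division times
    return np.round(c / cfg.frame_dt) * cfg.frame_dt


def simulate_population(config: SimulationConfig) -> list[NucleusTrack]:
    """Simulate a full population of nuclei and return their tracks.

    Radial dynamics per variant (overdamped Langevin, Euler-Maruyama at the
    frame cadence): ``low_c`` is a pure random walk with diffusivity D;
    ``gamma_c`` uses concentration-dependent noise
    D_eff = D cmax/(cmax - c) with c the live binned density; and
    ``external_force`` keeps the noise at D but adds the mean crowding drift
    D d/dr ln(cmax - c).  The final ``g2_fraction`` of each cycle is a
    deterministic apical run; divisions happen at the apical wall and spawn
    two daughters laterally offset by one nuclear radius.
    """
    cfg = config
    g = cfg.geometry
    growth = cfg.growth
    if cfg.divisions_enabled and not growth.divisions_absent:
        expected = growth.N0 * math.exp(cfg.duration / growth.tau)
        if expected > cfg.population_cap:
            raise ValueError(
                f"expected final population {expected:.0f} exceeds cap "
                f"{cfg.population_cap}: runaway growth")
        if cfg.duration < growth.TP:
            raise ValueError(
                "duration must cover at least one mean cell cycle when "
                "divisions are enabled")
    rng = np.random.default_rng(cfg.seed)
    pop = _Pop()
    n0 = int(growth.N0)

    # --- initial cohort ---------------------------------------------------
    r_min, r_max = cfg.r_min, cfg.r_max
    if cfg.initial_condition == "uniform":
        # uniform in volume between the reflecting walls
        u = rng.random(n0)
        r0 = (r_min**3 + u * (r_max**3 - r_min**3)) ** (1.0 / 3.0)
    else:  # apically weighted: exponential boundary layer at the apical wall
        depth = (r_max - r_min) / 4.0
        r0 = r_max - rng.exponential(depth, size=n0)
        r0 = _reflect(r0, r_min, r_max)
    cos_cap = 1.0 - g.Omega / (2.0 * math.pi)
    costh = rng.uniform(cos_cap, 1.0, size=n0)
    pop.theta = np.arccos(costh)
    pop.phi = rng.uniform(0.0, 2.0 * math.pi, size=n0)
    pop.r = r0
    pop.cycle = _draw_cycles(rng, n0, cfg)
    if cfg.divisions_enabled and not growth.divisions_absent:
        # stationary age distribution of an exponentially growing population:
        # f(age) ∝ 2^{-age/TP}; sampling it removes the start-up transient
        u = rng.random(n0)
        age = -growth.TP * np.log2(1.0 - u / 2.0)
        age = np.round(age / cfg.frame_dt) * cfg.frame_dt
        age = np.minimum(age, pop.cycle - cfg.frame_dt)
        pop.birth = -age
    else:
        pop.birth = np.zeros(n0)
        pop.cycle = np.full(n0, math.inf)
    pop.ids = np.arange(n0)
    pop.next_id = n0
    for i in range(n0):
        pop.parents[i] = None
        pop.traj[i] = []

    dt = cfg.frame_dt
    n_frames = int(round(cfg.duration / dt)) + 1
    v_ap = cfg.apical_speed
    divided: set[int] = set()

    def record(t: float) -> None:
        x = pop.r * np.sin(pop.theta) * np.cos(pop.phi)
        y = pop.r * np.sin(pop.theta) * np.sin(pop.phi)
        z = pop.r * np.cos(pop.theta)
        for i, nid in enumerate(pop.ids):
            pop.traj[nid].append((t, x[i], y[i], z[i]))

    for k in range(n_frames):
        t = k * dt
        record(t)
        if k == n_frames - 1:
            break
        age = t - pop.birth
        in_g2 = (cfg.divisions_enabled
                 & (age >= (1.0 - cfg.g2_fraction) * pop.cycle))
        # --- stochastic G1/S step ---
        free = ~in_g2
        nfree = int(free.sum())
        if nfree:
            xi_std = rng.standard_normal(nfree)
            rf = pop.r[free]
            if cfg.variant == "low_c":
                drift = 0.0
                D_eff = cfg.D
            elif cfg.variant == "gamma_c":
                c_here = _live_concentration(pop.r, cfg)[free]
                c_here = np.minimum(c_here, 0.95 * cfg.cmax)
                D_eff = cfg.D * cfg.cmax / (cfg.cmax - c_here)
                drift = 0.0
            else:  # external_force
                c_all, g_all = _live_concentration_gradient(pop.r, cfg)
                c_here = np.minimum(c_all[free], 0.95 * cfg.cmax)
                drift = -cfg.D * g_all[free] / (cfg.cmax - c_here)
                D_eff = cfg.D
            step = drift * dt + np.sqrt(2.0 * D_eff * dt) * xi_std
            pop.r[free] = _reflect(rf + step, r_min, r_max)
        # --- deterministic apical G2 run ---
        if np.any(in_g2):
            pop.r[in_g2] = np.minimum(pop.r[in_g2] + v_ap * dt, r_max)
        # --- divisions ---
        t_next = t + dt
        if cfg.divisions_enabled:
            due = (t_next - pop.birth) >= pop.cycle
            if np.any(due):
                keep = ~due
                # mitosis happens at the apical wall: snap any cell whose G2
                # run has not quite completed (short cycles) to r_max
                for i in np.flatnonzero(due):
                    nid = int(pop.ids[i])
                    divided.add(nid)
                    x = r_max * math.sin(pop.theta[i]) * math.cos(pop.phi[i])
                    y = r_max * math.sin(pop.theta[i]) * math.sin(pop.phi[i])
                    z = r_max * math.cos(pop.theta[i])
                    pop.traj[nid].append((t_next, x, y, z))
                n_new = 2 * int(due.sum())
                # daughters: parent's position, lateral offset ± one radius
                ang = cfg.nuclear_radius / np.maximum(pop.r[due], 1.0)
                dirn = rng.uniform(0, 2 * math.pi, size=int(due.sum()))
                th_p = np.repeat(pop.theta[due], 2)
                ph_p = np.repeat(pop.phi[due], 2)
                sgn = np.tile([1.0, -1.0], int(due.sum()))
                dth = np.repeat(ang * np.cos(dirn), 2) * sgn
                dph = np.repeat(ang * np.sin(dirn), 2) * sgn
                th_new = np.clip(th_p + dth, 1e-3, math.pi - 1e-3)
                ph_new = ph_p + dph
                r_new = np.full(n_new, r_max)
                ids_new = np.arange(pop.next_id, pop.next_id + n_new)
                parents_new = np.repeat(pop.ids[due], 2)
                pop.next_id += n_new
                cyc_new = _draw_cycles(rng, n_new, cfg)
                for nid, pid in zip(ids_new, parents_new):
                    pop.parents[int(nid)] = int(pid)
                    pop.traj[int(nid)] = []
                pop.r = np.concatenate([pop.r[keep], r_new])
                pop.theta = np.concatenate([pop.theta[keep], th_new])
                pop.phi = np.concatenate([pop.phi[keep], ph_new])
                pop.birth = np.concatenate([pop.birth[keep],
                                            np.full(n_new, t_next)])
                pop.cycle = np.concatenate([pop.cycle[keep], cyc_new])
                pop.ids = np.concatenate([pop.ids[keep], ids_new])
                if pop.ids.size > cfg.population_cap:
                    raise ValueError("population exceeded the hard cap")

    tracks = []
    for nid in sorted(pop.traj):
        rows = pop.traj[nid]
        if not rows:
            continue
        arr = np.array(rows)
        tracks.append(NucleusTrack(
            id=int(nid), parent_id=pop.parents[nid],
            birth_t=float(arr[0, 0]), t=arr[:, 0], xyz=arr[:, 1:4],
            fate="divided" if nid in divided else "censored"))
    return tracks


def apply_measurement_noise(tracks: Sequence[NucleusTrack], delta_r: float,
                            seed: int) -> list[NucleusTrack]:
    """Perturb each radial coordinate by an independent Uniform(-dr, +dr) draw.

    Positions are rescaled along the radius (the measured quantity is the
    apicobasal distance); lineage and times are untouched.  ``delta_r = 0``
    is the identity.
    """
    if delta_r < 0:
        raise ValueError("delta_r must be non-negative")
    rng = np.random.default_rng(seed)
    out = []
    for tr in tracks:
        if delta_r == 0.0:
            out.append(replace(tr, t=tr.t.copy(), xyz=tr.xyz.copy()))
            continue
        r = tr.r
        eps = rng.uniform(-delta_r, delta_r, size=r.size)
        scale = (r + eps) / np.where(r > 0, r, 1.0)
        out.append(replace(tr, t=tr.t.copy(), xyz=tr.xyz * scale[:, None]))
    return out


def sample_profiles_from_field(field, seed: int,
                               binspec=None, delta_r: float = 3.0):
    """Noisy concentration profiles drawn from a model concentration field.

    For every output time of the PDE solution ``field``: the nucleus count is
    a Poisson draw around the field's mass, positions are sampled from the
    radial density c(r) r², jittered within a grid cell, and perturbed by the
    uniform ±delta_r measurement error before binning with the standard
    error-box uncertainty model.  This reproduces the bin-count noise the
    concentration-profile pipeline sees on real tracked data.
    """
    from .profile import BinSpec, concentration_profile
    if binspec is None:
        binspec = BinSpec()
    g = field.geometry
    rng = np.random.default_rng(seed)
    nodes_r = field.xi_nodes * g.a
    cell = nodes_r[1] - nodes_r[0]
    masses = field.mass()
    profiles = []
    for k, t in enumerate(field.t_nodes):
        c = field.c_values[k]
        w = c * nodes_r**2
        N = int(rng.poisson(masses[k]))
        pos = rng.choice(nodes_r, size=N, p=w / w.sum())
        pos = pos + rng.uniform(-0.5, 0.5, N) * cell
        pos = pos + rng.uniform(-delta_r, delta_r, N)
        profiles.append(concentration_profile(
            np.clip(pos, g.b, g.a), g, binspec, delta_r=delta_r, t=float(t)))
    return profiles


_COLUMNS = ["track_id", "parent_id", "t_min", "x_um", "y_um", "z_um"]


def write_tracks(tracks: Sequence[NucleusTrack], path) -> None:
    """Write tracks as CSV (header `track_id,parent_id,t_min,x_um,y_um,z_um`).

    Missing parent is encoded as -1; coordinates at 1e-6 µm precision.
    """
    frames = []
    for tr in tracks:
        frames.append(pd.DataFrame({
            "track_id": tr.id,
            "parent_id": -1 if tr.parent_id is None else tr.parent_id,
            "t_min": tr.t, "x_um": tr.xyz[:, 0],
            "y_um": tr.xyz[:, 1], "z_um": tr.xyz[:, 2]}))
    df = (pd.concat(frames, ignore_index=True) if frames
          else pd.DataFrame(columns=_COLUMNS))
    df.to_csv(path, index=False, float_format="%.6f")


def read_tracks(path) -> list[NucleusTrack]:
    """Read a track CSV, validating structure and lineage.

    Raises ``ValueError`` naming the offending record for malformed rows,
    non-monotone or non-uniform sample times, or a parent_id that references
    no track in the file.
    """
    df = pd.read_csv(path)
    if list(df.columns) != _COLUMNS:
        raise ValueError(f"malformed header: {list(df.columns)}")
    if df.empty:
        return []
    ids = set(df["track_id"].unique().tolist())
    tracks = []
    children: dict[int, int] = {}
    for tid, grp in df.groupby("track_id", sort=True):
        t = grp["t_min"].to_numpy(dtype=float)
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise ValueError(f"track {tid}: sample times not strictly increasing")
        if t.size > 2 and not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
            raise ValueError(f"track {tid}: non-uniform frame interval")
        pid_vals = grp["parent_id"].unique()
        if pid_vals.size != 1:
            raise ValueError(f"track {tid}: inconsistent parent_id")
        pid = int(pid_vals[0])
        if pid != -1:
            if pid not in ids:
                raise ValueError(f"track {tid}: dangling parent_id {pid}")
            children[pid] = children.get(pid, 0) + 1
        tracks.append(NucleusTrack(
            id=int(tid), parent_id=None if pid == -1 else pid,
            birth_t=float(t[0]), t=t,
            xyz=grp[["x_um", "y_um", "z_um"]].to_numpy(dtype=float)))
    for tr in tracks:
        tr.fate = "divided" if children.get(tr.id, 0) == 2 else "censored"
    return tracks
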