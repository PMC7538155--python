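"""Stochastic single-nucleus simulations in a given concentration field.

Three overdamped Langevin variants for the radial motion of a nucleus after
its birth at the apical surface, all integrated with the Euler-Maruyama
scheme at a 0.2 min step:

* ``low_c``        — constant noise, dr = sqrt(2 D dt) N(0,1): dilute limit.
* ``gamma_c``      — concentration-dependent noise strength,
                     D_eff = D cmax / (cmax - c(r, t)): the stochastic force
                     is stronger where nuclei are crowded.
* ``external_force`` — constant noise plus the deterministic mean-field drift
                     v = D d/dr ln(cmax - c), the unique drift whose
                     Fokker-Planck equation matches the lattice-gas diffusion
                     model at constant noise (a reconstruction; the crowding
                     is felt as an ordinary force, not through the noise).

Cohorts of 40 nuclei reuse experimental birth times; repeating the cohort
2500 times gives min/max MSD envelopes per cell-cycle lag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as _dc_field
from typing import Sequence

import numpy as np

from .geometry import ShellGeometry
from .nonlinear import PDEGrid

__all__ = ["LangevinSpec", "MSDEnvelope", "simulate_nucleus",
           "simulate_cohort", "msd_envelope"]


@dataclass(frozen=True)
class LangevinSpec:
    """Study conditions for the single-nucleus simulations."""

    variant: str                   # low_c | gamma_c | external_force
    D: float                       # µm²/min
    geometry: ShellGeometry
    field: PDEGrid | None = None   # c(r, t); required by the crowding variants
    cmax: float = 4.12e-3          # µm⁻³
    dt: float = 0.2                # min
    duration_per_nucleus: float = 150.0   # min
    birth_times: np.ndarray = _dc_field(default_factory=lambda: np.zeros(40))
    n_reps: int = 2500
    seed: int = 0
    reflecting: bool = True

    def __post_init__(self) -> None:
        if self.variant not in ("low_c", "gamma_c", "external_force"):
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.variant != "low_c" and self.field is None:
            raise ValueError(f"variant {self.variant!r} needs a concentration field")
        if self.field is not None:
            bt = np.asarray(self.birth_times, dtype=float)
            if np.any(bt < self.field.t_nodes[0] - 1e-9) or \
               np.any(bt + self.duration_per_nucleus >
                      self.field.t_nodes[-1] + 1e-9):
                raise ValueError("birth times (+duration) outside the field's span")


def _field_lookup(spec: LangevinSpec, r: np.ndarray, t: float) -> np.ndarray:
    """c at nucleus positions: average of the two closest spatial grid values,
    nearest time slice."""
    grid = spec.field
    k = int(np.argmin(np.abs(grid.t_nodes - t)))
    row = grid.c_values[k]
    xi = r / spec.geometry.a
    nodes = grid.xi_nodes
    j = np.clip(np.searchsorted(nodes, xi), 1, nodes.size - 1)
    return 0.5 * (row[j - 1] + row[j])


def _field_gradient(spec: LangevinSpec, r: np.ndarray, t: float) -> np.ndarray:
    """dc/dr at nucleus positions (µm⁻⁴), nearest time slice."""
    grid = spec.field
    k = int(np.argmin(np.abs(grid.t_nodes - t)))
    row = grid.c_values[k]
    a = spec.geometry.a
    g = np.gradient(row, grid.xi_nodes * a)
    return np.interp(r / a, grid.xi_nodes, g)


def _reflect(r: np.ndarray, lo: float, hi: float) -> np.ndarray:
    span = hi - lo
    y = np.mod(r - lo, 2 * span)
    y = np.where(y > span, 2 * span - y, y)
    return lo + y


def _step_cohort(spec: LangevinSpec, r: np.ndarray, t: float,
                 noise: np.ndarray) -> np.ndarray:
    """One Euler-Maruyama step for an array of walkers (any shape)."""
    dt = spec.dt
    if spec.variant == "low_c":
        drift = 0.0
        D_eff = spec.D
    else:
        c = _field_lookup(spec, r, t)
        c = np.minimum(c, spec.cmax * (1.0 - 1e-9))
        if np.any(c >= spec.cmax):
            raise RuntimeError("concentration at walker position reached cmax")
        if spec.variant == "gamma_c":
            drift = 0.0
            D_eff = spec.D * spec.cmax / (spec.cmax - c)
        else:  # external_force
            gradc = _field_gradient(spec, r, t)
            drift = -spec.D * gradc / (spec.cmax - c)
            D_eff = spec.D
    r_new = r + drift * dt + np.sqrt(2.0 * D_eff * dt) * noise
    if spec.reflecting:
        r_new = _reflect(r_new, spec.geometry.b, spec.geometry.a)
    return r_new


def simulate_nucleus(spec: LangevinSpec, birth_t: float, r0: float,
                     rng: np.random.Generator) -> np.ndarray:
    """Radial trajectory of one nucleus from its birth, sampled every dt."""
    if not spec.geometry.b <= r0 <= spec.geometry.a:
        raise ValueError("r0 outside [b, a]")
    n = int(round(spec.duration_per_nucleus / spec.dt)) + 1
    traj = np.empty(n)
    traj[0] = r0
    r = np.array([r0])
    for k in range(1, n):
        t = birth_t + (k - 1) * spec.dt
        r = _step_cohort(spec, r, t, rng.standard_normal(1))
        traj[k] = r[0]
    return traj


def simulate_cohort(spec: LangevinSpec, rng: np.random.Generator | None = None,
                    r0: float | None = None) -> np.ndarray:
    """All cohort nuclei, aligned to birth: array (n_nuclei, n_steps+1).

    Each nucleus starts at the apical division position (``r0`` defaults to
    one nuclear radius-free apical start at r = a) at its own birth time;
    subtracting birth times is implicit in the alignment of the output rows.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    if r0 is None:
        r0 = spec.geometry.a - 3.5
    births = np.asarray(spec.birth_times, dtype=float)
    n_nuc = births.size
    n = int(round(spec.duration_per_nucleus / spec.dt)) + 1
    out = np.empty((n_nuc, n))
    out[:, 0] = r0
    r = np.full(n_nuc, float(r0))
    for k in range(1, n):
        t_per_nuc = births + (k - 1) * spec.dt
        if spec.variant == "low_c":
            r = _step_cohort(spec, r, 0.0, rng.standard_normal(n_nuc))
        else:
            # field lookup is per-nucleus in time: step each birth-time group
            noise = rng.standard_normal(n_nuc)
            for t in np.unique(t_per_nuc):
                m = t_per_nuc == t
                r[m] = _step_cohort(spec, r[m], float(t), noise[m])
        out[:, k] = r
    return out


def cohort_msd(trajectories: np.ndarray) -> np.ndarray:
    """Cohort-mean squared radial displacement from birth per lag."""
    disp2 = (trajectories - trajectories[:, :1]) ** 2
    return disp2.mean(axis=0)


@dataclass(frozen=True)
class MSDEnvelope:
    """Pointwise min/max (and mean) of the cohort-mean MSD across repetitions."""

    lags: np.ndarray    # min
    lower: np.ndarray   # µm²
    upper: np.ndarray   # µm²
    mean: np.ndarray | None = None   # µm², across-repetition average


def msd_envelope(spec: LangevinSpec) -> MSDEnvelope:
    """Min/max envelope of the cohort MSD over ``n_reps`` repetitions."""
    if spec.n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(spec.seed)
    births = np.asarray(spec.birth_times, dtype=float)
    n_nuc = births.size
    n = int(round(spec.duration_per_nucleus / spec.dt)) + 1
    r0 = spec.geometry.a - 3.5
    # vectorize over (reps, nuclei)
    r = np.full((spec.n_reps, n_nuc), r0)
    start = r.copy()
    msd = np.empty((spec.n_reps, n))
    msd[:, 0] = 0.0
    for k in range(1, n):
        t_per_nuc = births + (k - 1) * spec.dt
        noise = rng.standard_normal((spec.n_reps, n_nuc))
        if spec.variant == "low_c":
            r = _step_cohort(spec, r, 0.0, noise)
        else:
            for t in np.unique(t_per_nuc):
                m = t_per_nuc == t
                r[:, m] = _step_cohort(spec, r[:, m], float(t), noise[:, m])
        msd[:, k] = ((r - start) ** 2).mean(axis=1)
    return MSDEnvelope(lags=np.arange(n) * spec.dt,
                       lower=msd.min(axis=0), upper=msd.max(axis=0),
                       mean=msd.mean(axis=0))
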