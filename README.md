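# iknm — nuclear crowding and nonlinear diffusion in the developing retina

During interkinetic nuclear migration (IKNM), the nuclei of retinal
progenitor cells divide at the apical surface of the pseudostratified
neuroepithelium and then wander stochastically toward the basal side for
most of the cell cycle.  Because every division injects a nucleus at the
apical wall, a concentration gradient builds up across the tissue, and the
population-level motion resembles diffusion down that gradient even though
no force acts on any individual nucleus deterministically.

`iknm` is a Python toolkit for the tissue-scale analysis of this process,
aimed at quantitative developmental biologists and biophysicists working
with 3-D nuclear tracking data (light-sheet or two-photon).  It provides:

* **Synthetic tracking data** — seeded populations of nuclei in a spherical
  shell sector (apical radius *a*, basal radius *b*), with exponential
  growth *N(t) = N₀ e^{t/τ}* (τ = T_P/ln 2), apical-only divisions, a rapid
  apical G2 run (~8 % of the cycle), a drug-block mode without divisions,
  and uniform ±3 µm radial measurement noise.  CSV in/out with lineage.
* **Track statistics** — apicobasal coordinates, signed speeds over the
  normalized cell cycle, neighbor-speed correlations in cylindrical
  neighborhoods, and the birth-aligned mean-squared-displacement curve.
* **Concentration profiles** — radial binning with the error-box
  uncertainty model: E(N_bin) = Σₙ p_{n,bin}, Var(N_bin) = Σₙ p_{n,bin}(1−p_{n,bin}),
  exact spherical bin volumes V_bin = Ω(r³_out − r³_in)/3.
* **Linear diffusion model** — the exact eigenfunction solution of
  ∂c/∂t = (D/r²)∂_r(r² ∂_r c) on b ≤ r ≤ a with the growing apical influx
  D ∂_r c|_a = N₀/(S τ) e^{t/τ} and basal no-flux, including the projection
  of a measured initial profile onto the radial Neumann eigenmodes.
* **Nonlinear (lattice-gas) model** — finite nuclear volume enters through
  a maximum packing concentration c_max, giving
  ∂c/∂t = (D/r²)∂_r(r² c_max/(c_max−c) ∂_r c); solved by a conservative
  method-of-lines scheme with stiff time integration.
* **Fitting** — minimal-χ² grid scan for D with the effective-variance
  error model σ² = σ_y² + (σ_x dc/dξ)², pooled over time points; σ_D from
  the curvature of the time-averaged χ²(D) curve; fit probability P(χ²;ν);
  bin-width selection; Welch's t-test for cross-condition comparison.
* **Biophysical interpretation** — Stokes–Einstein reference diffusivity,
  drag in a tight-fitting membrane tube, the stochastic-force strength
  Γ = 6ζ²D and the force scale √(Γ/τ_c), close-packing c_max.
* **Cell shapes** — equilibrium axisymmetric membrane shapes around the
  nucleus from the Helfrich energy E = ∫dS(κH²/2 + γ), with a spherical
  contact arc and curvature-matched contact points.
* **Langevin simulations** — single-nucleus trajectories (Euler–Maruyama,
  0.2 min steps) under three noise models: dilute (constant D), crowding-
  dependent noise D_eff = D c_max/(c_max−c), or an explicit crowding force;
  min/max MSD envelopes over repeated 40-nucleus cohorts.

## Worked example

```python
import numpy as np
from iknm import ShellGeometry, GrowthLaw
from iknm.nonlinear import solve_nonlinear
from iknm.synthetic import sample_profiles_from_field
from iknm.fitting import scan_D
from iknm.biophysics import report

geom = ShellGeometry(a=100.0, b=45.0)          # half shell, 55 µm thick
cmax = 4.12e-3                                  # µm⁻³, close packing at R=3.5 µm

# ground truth: crowding model at D = 0.09 µm²/min, influx on
ic = lambda x: 0.55 * cmax * np.exp((x - 1.0) * 7.0) + 3e-4
xi = np.linspace(geom.rho, 1.0, 400)
N0 = np.trapezoid(geom.Omega * geom.a**3 * xi**2 * ic(xi), xi)
growth = GrowthLaw(N0=N0, TP=300.0)
field = solve_nonlinear(ic, 0.09, cmax, geom, growth,
                        np.arange(0.0, 200.1, 2.0))

# noisy synthetic profiles, then refit D by the pooled chi-square scan
profiles = sample_profiles_from_field(field, seed=12345)
fit = scan_D(profiles, geom, growth, model="nonlinear", cmax=cmax,
             grid=np.arange(0.01, 0.41, 0.01), n_nodes=150)
print(f"D* = {fit.D_star:.2f} ± {fit.sigma_D:.2f} µm²/min, "
      f"P(chi²; {fit.nu}) = {fit.P_chi:.2f}")

rep = report(D=fit.D_star, R=3.5)
print(f"thermal reference: {rep['D_thermal_um2_min']:.1f} µm²/min "
      f"({rep['thermal_over_fitted']:.0f}x the fitted value)")
```

Output:

```
D* = 0.08 ± 0.03 µm²/min, P(chi²; 15) = 0.14
thermal reference: 4.2 µm²/min (52x the fitted value)
```

The recovered diffusion constant matches the generating value to within its
standard deviation, and the Stokes–Einstein diffusivity of a 3.5 µm sphere
in water is ~50× larger — the nuclei are far less mobile than free thermal
particles, pointing at membrane confinement plus active (cytoskeletal)
forcing rather than thermal motion.

A `iknm` command-line interface wraps the same functionality
(`iknm simulate-tracks`, `iknm profile`, `iknm fit`, `iknm biophys`,
`iknm shape`, `iknm langevin`, ...); every command reads and writes plain
CSV/TSV/JSON/YAML.

## Layout

```
src/iknm/
  geometry.py    shell geometry, growth law, shell volumes
  synthetic.py   seeded track generator, measurement noise, CSV I/O
  tracks.py      apicobasal conversion, kinematics, correlations, MSD
  profile.py     binned concentration profiles with x/y uncertainties
  linear.py      eigenfunction solution of the linear model
  nonlinear.py   lattice-gas PDE solver
  fitting.py     chi-square scan, sigma_D, P_chi, Welch tests
  biophysics.py  physical interpretation of D
  membrane.py    Helfrich shapes around the nucleus
  langevin.py    single-nucleus stochastic simulations
  cli.py         command-line interface
```
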