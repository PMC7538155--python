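# Methods

This note documents the models implemented in `iknm`, their assumptions,
the numerical choices behind them, and what the synthetic data do and do
not emulate.

## Tissue model and coordinates

The retinal neuroepithelium is idealized as a sector of a spherical shell
centred on the lens: basal surface at radius `b`, apical surface at `a`,
solid angle `Omega`.  All analysis runs in the dimensionless radius
`xi = r/a` (with `rho = b/a`) and dimensionless time `s = D t / a²`.  The
default geometry is `a = 100 µm`, `b = 45 µm`, `Omega = 2π` — a half shell
of 55 µm tissue thickness.  The apical radius is a stand-in: it is not
directly measured in typical datasets, and all fitted quantities that
depend on it do so only through the ratio `rho` and the sector volume, both
of which are config-overridable.

Nucleus counts grow exponentially, `N(t) = N0 exp(t/τ)` with
`τ = TP / ln 2` and `TP` the mean cell-cycle length (300 min default;
205.5 min and 532.78 min are the measured values at raised and lowered
incubation temperature and appear in the cross-condition comparison).  The
influx of nuclei through the apical surface is `dN/dt / S` with
`S = Omega a²`.

## Linear model

Ordinary diffusion of the nuclear concentration in the shell,

    dc/dt = (D/r²) d/dr (r² dc/dr),
    D dc/dr|_{r=a} = N0/(S τ) e^{t/τ},      dc/dr|_{r=b} = 0,

has the closed-form solution

    c(xi, s) = Σ_i [ h_i e^{−λ_i² s} + α_i f0/(σ+λ_i²) e^{σ s} ] H_i(xi)
             + f0 e^{σ s} (xi²/2 − ρ xi + g0)/(1−ρ),

with `σ = a²/(D τ)` and `f0 = N0 a/(S τ D)`.  The `H_i` are the radial
Neumann eigenmodes of the spherical Laplacian (no-flux at both walls),
normalized under the weight `xi²`; eigenvalues come from bracketed Brent
root-finding on the transcendental condition assembled from `sin(λξ)/ξ` and
`cos(λξ)/ξ`, and are verified in the tests against an independent
finite-difference eigensolver (Richardson-extrapolated, 4-digit agreement).

Three coefficients are derived rather than quoted:

* `g0` follows from mass consistency: the eigenmodes carry no net mass, so
  the quadratic particular term alone must reproduce the influx, fixing
  `σ ∫ xi² u dxi = 1` for `u = (xi²/2 − ρ xi + g0)/(1−ρ)`.  The same
  condition makes the volume integral of the `s = 0` particular term equal
  `N0` identically (because `f0/σ = N0/(Omega a³)`), so the separately
  stated initial-mass constraint is automatic.
* `α_i` are minus the `xi²`-weighted projections of the residual left when
  the quadratic term is substituted into the PDE.
* `h_i` come from projecting a measured (binned) initial profile:
  `h̃_i = Σ_m xi_m² H_i(xi_m) c(xi_m) Δxi_m − (f0/(1−ρ)) ∫ xi² H_i u dxi`,
  then `h_i = h̃_i − α_i f0/(σ+λ_i²)`.

All three are validated against a brute-force method-of-lines integration
of the same initial-value problem (max relative error < 1 % over 200 min).

**Truncation.**  The series is truncated at `M = 8` modes by default.  Note
one consequence: the quadratic particular term has a nonzero apical slope
(that is how it carries the influx), so it violates the homogeneous
Neumann condition of the eigenbasis and its eigen-expansion converges only
algebraically.  The `s = 0` reconstruction of a smooth profile is therefore
accurate to ~7 % at `M = 8` (improving to ~2 % at `M = 24`); the error
decays as `e^{−λ² s}` and does not move the fitted `D`.  A related
constraint: because the constant mode is excluded (its bookkeeping lives in
`g0`), the projection can only represent initial profiles whose volume
integral equals `N0`.  That holds by construction when `N0` is the initial
tracked count; `build_solution` warns if the supplied growth law disagrees
with the profile mass by more than 5 %.

## Nonlinear (lattice-gas) model

Finite nuclear volume enters through a maximum packing concentration
`cmax`, replacing the ideal-gas entropy by the lattice-gas form and giving

    dc/dt = (D/r²) d/dr [ r² cmax/(cmax−c) dc/dr ],

with the influx condition carrying the same `cmax/(cmax−c)` factor.  The
default `cmax = 4.12e−3 µm⁻³` is the close-packing density of 3.5 µm
spheres (`π/(3√2) ≈ 0.74` packing fraction over `(4/3)πR³`); the admissible
range `1.41e−3 … 6.55e−3 µm⁻³` corresponds to nuclear radii 5 µm to 3 µm.

The solver is a conservative finite-volume method-of-lines scheme on a
uniform radial grid (400 cells by default; fits use 150–200 cells, which
the self-convergence test shows is within 0.2 % of the refined solution):
fluxes on faces, exact spherical cell factors `(r_+³ − r_−³)/3`, boundary
fluxes imposed directly, LSODA with a tridiagonal band for time stepping.
Mass balance then holds to solver tolerance (checked: < 1 % against the
growth law with influx on, < 0.5 % drift with influx off).  Concentrations
within `1e−6` of `cmax` abort with a close-packing error; during a `D`
scan such an abort marks that `D` as unable to describe the data (infinite
χ²) rather than failing the scan.  In the `cmax → ∞` limit the solver
reproduces the linear closed form to < 1 %, which is the main cross-check
tying the two models together.

The nonlinear model always starts from the linear model's projected
initial condition so that the two fits are comparable.

## Concentration profiles and the uncertainty model

Each measured radial position carries a uniform error box of half-width
`Δr = 3 µm`.  The probability that nucleus `n` lies in a bin is the
fractional overlap of its box with the bin, giving
`E(N) = Σ p_n` and `Var(N) = Σ p_n(1−p_n)` per bin; dividing by the exact
shell-bin volume yields `c` and `σ_y`.  The bin-centre position error is
taken as `σ_x = sqrt(bin width · 1 µm)` (i.e. numerically the square root
of the bin width in µm), converted to ξ-units by dividing by `a`; the
1 µm reference scale makes the square root dimensionally explicit, and the
scaling is exposed should a different convention be preferred.  Bins are
laid from the basal edge upward, a final partial apical bin keeps its true
volume, and bins whose centres fall within the apical/basal exclusion
zones (default 4 µm; nuclear centres cannot approach a wall closer than
one radius) are excluded from fitting but retained in the profile.

One systematic consequence, measured and pinned in the tests: the error
box convolves every profile with a ±3 µm box (twice when the physical
measurement displacement is also simulated), adding ~3–6 µm² of apparent
spread.  When the true spreading over the fit window is comparable —
`2 D t ≈ 10 µm²` at `D = 0.05` over 100 min — the fitted `D` absorbs part
of it and comes out high by ~0.05 µm²/min.  At the tissue's fitted scale
(`D ≈ 0.09`, `2Dt ≈ 18–36 µm²`) the effect is inside `σ_D`.

## Fitting

`χ² = Σ_m (c_exp − c_model)²/σ_m²` with the effective variance
`σ_m² = σ_y² + (σ_x · dc/dξ)²`.  `D` is scanned on a discrete grid
(0.01 to 10 µm²/min in 0.01 steps by default; analyses of the crowding
model use the physically relevant sub-decade 0.01–0.4 to keep scans fast,
a pure problem-size choice — the χ² curve is monotone far from the
minimum).  Pooled fits sum χ²(D) over all time points (first 100 time
points / 200 min by default); ties break toward smaller `D` and a boundary
minimum is flagged.  `σ_D` comes from the quadratic width at `Δχ² = 1` of
the **time-averaged** curve — the averaged-curve width is `√n_t` times the
summed-curve width and empirically matches the seed-to-seed scatter of
`D*`, which the summed-curve width underestimates because all time points
share one initial condition.  `P(χ²; ν)` with `ν = (fitted bins) − 1` is
the upper tail of the χ² distribution and should sit near 0.5 for a
correct model; bin-width selection picks the candidate whose median
`P(χ²; ν)` over time points is closest to 0.5.  Cross-condition
comparisons use Welch's unequal-variances t-test with `n = 100` per group
(the number of pooled time points); the time points are not strictly
independent, which limits the test's predictive power — no correction is
applied.

## Synthetic tracks

The generator emulates the statistical structure of curated tracking data:
frame interval 2 min; per-cell cycle lengths from a truncated normal
(mean `TP`, CV 0.15, floored at the G2 duration); the final 8 % of each
cycle is a deterministic apical run whose default speed completes the run
from the basal-most position; mitosis happens at the apical wall and
spawns two daughters offset laterally by one nuclear radius; reflecting
walls at `b + R` and `a − R` (R = 3.5 µm); initial ages sampled from the
stationary age distribution of an exponentially growing population (no
start-up transient); uniform ±3 µm radial measurement noise applied at
export.  G1/S motion is an overdamped random walk, either with constant
`D` (`low_c`), with crowding-dependent noise coupled to the live binned
concentration of the population itself (`gamma_c`, self-consistent
mean-field), or with a crowding drift at constant noise
(`external_force`).  The early-G1 basal "burst" seen in real speed
distributions is not modelled separately; in the `gamma_c` variant it
emerges from crowding at the apical wall, where daughters are born.

What passing tests on these data show: the analysis chain (coordinates →
profiles → fits) is internally consistent and recovers known parameters
under the stated noise.  What they do not show: robustness to tracking
errors (broken/merged tracks), lateral tissue inhomogeneity, nuclear shape
changes, or drift in the late, apical-return phase of the cycle — none of
which the generator produces.

## Langevin simulations

Single nuclei follow `ζ dr/dt = F(t)` in one radial dimension,
discretized by Euler–Maruyama at `dt = 0.2 min` (halving `dt` changes
cohort MSDs within sampling error).  Noise conventions: the radial MSD of
the dilute model is `2 D lag` (1-D convention, matching the track
statistics); the `Γ = 6 ζ² D` bookkeeping in the biophysics module is the
3-D relation and is kept separate.  The concentration field for the
crowding variants comes from the nonlinear model; `c` at a walker is the
average of the two nearest grid values at the nearest stored time.  The
noise amplitude is evaluated at the pre-step position (Itô convention).
Walls at `b` and `a` reflect.

The `external_force` drift is a reconstruction: the unique drift,
`v = D d/dr ln(cmax − c)`, that makes the constant-noise model's
Fokker–Planck equation coincide with the lattice-gas equation in the
mean-field limit.

**Itô vs mean-field, reported.**  Drift-free multiplicative noise does not
exactly sample the lattice-gas equation — its Fokker–Planck form has an
extra `div(c dD_eff/dr)` term.  Measured at `t = 100 min` on a crowded
field: up to ~13 % of the peak concentration at the apical wall, < 8 %
in the interior; walkers carrying the exact correction drift
(`D'_eff + 2 D_eff/r`) match the PDE to < 5 %.  The closure test asserts
both numbers.

Cohort simulations use 40 nuclei with prescribed birth times, 150 min
each, and build min/max MSD envelopes across repetitions (2500 by default;
the bundled analyses use 500, which already separates the models cleanly).
The stable discrimination statistic is the across-repetition mean MSD of
the crowding-noise model: it lies inside its own envelope and escapes the
dilute and crowding-force envelopes at late lags, reproducing the
observation that only concentration-dependent noise matches tissue data.

## Biophysical interpretation

With water viscosity at 25 °C (`9e−4 Pa·s`) and `R = 3.5 µm`,
Stokes–Einstein gives `D_thermal ≈ 4.2 µm²/min`, ~50× the fitted
`D ≈ 0.09 µm²/min`.  Confinement in a tight membrane tube suppresses
mobility by `ζ_tube/ζ_0 = (3/2)[(κ/k_BT)(γR²/k_BT)]^{2/3} ≈ 6e5` (with
`κ = 20 k_BT` and tension set by `γ = k_BT/ℓ²`, `ℓ = 1 nm` — the only
choice consistent with `γR²/k_BT ~ 10⁷`; the looser bound `γ ≲ 1e−5 J/m²`
quoted for membranes generally is inconsistent with that ratio and is not
used).  Neither limit matches the data, implying active forcing: the
stochastic force strength `Γ = 6ζ²D` spans `~1.2e−18…3.4e−17 N²·s` for
drags `2e5…1e6 × ζ_0` (the band, not its endpoints, is the contract), and
correlation times of 10 ms–1 s give forces of 1–50 nN, compatible with
cooperative cytoskeletal transport.

## Membrane shapes

Stationary shapes of the axisymmetric Helfrich energy obey
`−γH + 2κ(H³ − KH) + κΔH = 0` with
`H = δ_zz/(1+δ_z²)^{3/2} − 1/(δ√(1+δ_z²))` and
`K = −δ_zz/(δ(1+δ_z²)²)`.  The free region from each cell end (radii
`δ_a = 1.98 µm`, `δ_b = 0.94 µm`, length `L = 55 µm`) is solved as a
fourth-order collocation BVP; around the nucleus the membrane is a
spherical arc of radius `R_tube = R + gap` (gap 0 by default), and the
contact point is iterated until `δ`, `δ_z` and the mean curvature are
continuous.  Curvature convention: evaluating the axisymmetric `H` on the
arc gives `−2/R_tube`, twice the "circle" value `−1/R_tube` sometimes
quoted; the default matches `H` computed by the same formula on both sides
of the junction (`contact_curvature="eq_arc"`), and the `"half"` option
reproduces the other reading.  The matched contact point is the
constrained energy optimum: energy decreases toward it along the feasible
branch, and beyond it the free solution would cut through the nucleus
(verified in the tests).  Necks scale as `sqrt(κ/γ)` — the printed ratio
`κ/γ` is dimensionally a length squared, so the square-root scaling is the
implemented reading.  Demonstration tensions use `γR²/κ` up to ~10³
(γ ≤ ~80 κ/µm²); the physically estimated `~10⁵–10⁷` regime produces
necks too thin for reliable collocation and is out of numerical scope.

## Problem sizes

Defaults for bundled analyses and tests, chosen as the package's own
balance of statistical power against run time: PDE grids of 150–400 cells;
`D` scans over 30–40 grid points in the physical sub-decade; parameter
recovery over 100 time points with ~2000–3200 nuclei per frame; 5 seeds
per recovery condition; Langevin envelopes from 500 repetitions of
40-nucleus cohorts; population simulations up to 900 min / ~800 nuclei.
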