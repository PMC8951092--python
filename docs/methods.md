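# Methods

## Scope and workflow

`rodchar` characterizes rodlike polyelectrolytes in dilute electrolyte from
four kinds of bench data: (i) viscosity dilution series, (ii) density
dilution series, (iii) electrophoretic mobility + diffusion (LDV/DLS)
records, and (iv) end-to-end-distance tables from chain simulations.  The
stages compose as densitometry → viscometry → slender-body inversion →
electrokinetics; each is usable on its own.

## Slender-body model

The blunt-cylinder intrinsic viscosity (volume-fraction convention) is

    f(lam) = (3/15) lam^2/(ln 2lam - 0.5) + (1/15) lam^2/(ln 2lam - 1.5) + 14/15.

Assumptions: rigid rod, aspect ratio lam = Lc/dc much larger than 1, zero
shear rate, no excluded-volume or flexibility corrections.  `f` has a pole at
lam = e^1.5/2 ≈ 2.24 and is strictly increasing above it; any intrinsic
viscosity above f(3) ≈ 3.8 therefore inverts uniquely.

**Exact inversion** brackets the root on lam ∈ [3, 1e6] and solves with
Brent's method (relative tolerance 1e-13, i.e. residuals below 1e-10 in
[eta]).  The lower bound 3 is the adopted validity cutoff; results with
lam < 10 are logged as marginal, since "slender" presumes lam ≫ 1.

**One-step inversion** uses the closed formula seeded by
lam1 = (15 [eta])^(1/2):

    lam = { 15 [eta] / [ 3/(ln 2lam1 - 0.5) + 1/(ln 2lam1 - 1.5) ] }^(1/2).

Measured accuracy against the exact inversion: 3.4% at [eta] = 50, below 3%
for [eta] ≳ 57, below 1% for [eta] ≳ 160.  The commonly quoted "≈1% above
50" is optimistic at the low end; prefer the exact inversion unless the
closed form is specifically wanted.  An optional fixed-point mode
re-substitutes lam until |Δlam|/lam < 1e-10; note it converges to the fixed
point of the truncated map (the additive 14/15 term is absent from the
one-step formula), which still differs from the exact inverse by ~0.5–1%.

**Derived properties.**  With the molecule volume vp known (from densitometry
and a nominal molar mass), the equivalent cylinder has
dc = (4 vp / (pi lam))^(1/3), Lc = lam dc; otherwise the extended-chain
diameter of the polymer spec is used and vp follows from the geometry.  Then
dH = lam dc/(ln 2lam - 0.11), D = kT/(3 pi eta dH), Rg = Lc/sqrt(12)
(thin-rod limit), and Sc = dH/ds with ds = (6 vp/pi)^(1/3).  The molar mass
uses Mm = (M1 dc / lm) lam with the condition-specific cylinder diameter.
Displayed aspect ratios are rounded to integers; all chained computation uses
unrounded values.

**Interpolants.**  `fit_interpolants` samples the exact inversion on a
log-uniform [eta] grid (default 200 points on [50, 600]; the published
working range) and fits lam = C [eta]^b by log-log least squares — the molar
mass and gyration radius are the same fit scaled by Cm = M1 dc/lm and
dc/sqrt(12) — and offset forms a + C [eta]^b for dH and Sc by
Levenberg–Marquardt initialized from the log-log fit of the
offset-subtracted curve (initial offset: half the curve minimum).  Fits are
validated by rms relative error (< 5% required; observed ≲ 0.5%), not by
matching any particular printed coefficients: a power law is only an
approximation to the logarithmic exact curve, so fitted coefficients depend
on the grid and range.

## Viscometry

The relative viscosity eta_r = eta_p/eta_e is converted to the reduced
specific viscosity (eta_r - 1)/Phi_V with Phi_V = c_b/rho_p, and a straight
line in Phi_V is extrapolated to zero concentration; the intercept is [eta]
and the slope the quadratic (Huggins-type) coefficient.  Note the raw ratio
eta_r/Phi_V sometimes quoted for this construction diverges as Phi_V → 0;
the finite-intercept quantity is the reduced *specific* viscosity, which is
what this package fits.

Records with eta_r ≥ 1.2 are outside the dilute regime and excluded with a
warning rather than failing the run.  The default fit is unweighted OLS.
With relative (multiplicative) viscometer noise the reduced viscosity has
error ∝ 1/Phi_V, so an inverse-variance option (weights Phi_V²,
`weights="volume_fraction_squared"`, `--weighted` on the CLI) is provided
and recommended for noisy data.  Even with matched weights, multiplicative
noise of level s leaves an *absolute* uncertainty on the intercept of order
s·(a few hundred) for the 50–500 mg/L design — about ±60 per series at
s = 1%, or ±3 on the median of 500 replicates.  Relative recovery targets
(e.g. 2%) are therefore only meaningful for large intrinsic viscosities;
at [eta] ≈ 60 the same absolute floor is ~5%.

## Densitometry and geometry

The dilution fit of rho_sol/rho_sys vs mass fraction w_p fixes the intercept
at 1 (rho_sys → rho_sol as w_p → 0 by construction) and estimates the slope
s_p through origin; a free-intercept diagnostic is logged.  Then
rho_p = rho_sol/(1 + s_p).  Volumes: nu_1 = 1e27·M1/(Av rho_p) nm³ per
monomer and v_m = 1e27·Mn/(Av rho_p) per molecule (Avogadro constant fixed
at 6.02214076e23 1/mol).  The cylinder relation Le = 4 v_p/(pi dc²) and the
equal-volume sphere d_s = (6 v_p/pi)^(1/3) complete the chain.  Known
wrinkle: one published compilation lists 4.73 nm for the sphere diameter at
v_p = 46.5 nm³, but the formula it cites gives 4.46 nm; this package follows
the formula.

## Electrokinetics

Debye length kappa^-1 = (eps kT / (2 e² NA·10³ I))^(1/2) with the ionic
strength taken as the nominal 1:1 salt concentration (H+/OH- neglected; this
reproduces the measured screening lengths for I ≥ 1e-4 M).  Hydrodynamic
diameter from DLS via Einstein–Stokes; effective charge from the
Lorentz–Stokes relation q_e = kT mu_e/D (equivalently 3 pi eta dH mu_e), the
charge number N_c = q_e/e and ionization degree alpha* = N_c/N_monomers.
The zeta potential uses the Debye–Hückel–Henry model
zeta = 3 eta mu_e / (2 eps f(kappa a)) with a = dH/2 and Henry's function by
Ohshima's closed form f = 1 + 1/2 [1 + 2.5/(kappa a (1 + 2 e^-kappa a))]^-3
(accurate to ~1% across all kappa a; the specific choice of Henry-function
approximation is recorded here because only the model family is standard).
Relaxation (O'Brien–White) and soft-layer corrections are out of scope, so
zeta values beyond ~50 mV are model-dependent estimates.

Mobilities are accepted in the instrument unit μm·cm/(V·s) (×1e-8 to SI)
at the CSV/CLI boundary; everything internal is SI.

Default physical context: T = 298.15 K, eta = 0.890 mPa·s, eps_r = 78.5,
rho_sol = 997 kg/m³ (water at 298 K) — all overridable per call or per CLI
flag.

## Chain-geometry analysis

End-to-end (EtE) tables are consumed either as per-frame long CSVs or as
summary rows.  The length-per-monomer fit Le = la·Nm is through-origin
(slope = Σ Nm·Le / Σ Nm²), since the model is strictly proportional; a
free-intercept diagnostic is logged.  The "maximum" mode estimates the
extended-chain monomer length from per-row maxima over frames (no outlier
trimming); "average" mode gives the ensemble-average length per monomer.
Chain diameter from the cylinder model: dc = (4 v_m/(pi L))^(1/2).

## Synthetic data

Generators are pure functions of (seed, config) and emulate:

* **viscometry** — 10 concentrations evenly spaced on 50–500 mg/L,
  eta_r = 1 + [eta] Phi + kH ([eta] Phi)², default Huggins coefficient
  kH = 0.3 (typical polyelectrolyte value), multiplicative Gaussian noise on
  eta_p (instrument-like relative error);
* **densitometry** — mass fractions on [0, 5e-4], exact linear law, additive
  Gaussian noise with the densitometer's 5e-3 kg/m³ absolute precision as
  default;
* **chains** — a freely rotating chain with fixed bond length; the
  `stiffness` parameter is the cosine of the bond angle, so 1 gives a
  straight rod with EtE = (Nm−1)·b and 0 the ideal random-walk limit
  (mean EtE ∝ sqrt(Nm)).  Because EtE carries Nm−1 bonds, the
  through-origin slope of stiff-chain maxima equals b·(1 − ΣNm/ΣNm²):
  bond-length recovery to sub-percent accuracy requires long chains
  (Nm ≳ 200), which is how the recovery checks are run;
* **electrokinetics** — diffusion from Einstein–Stokes of a true dH and
  mobility from the exact Lorentz–Stokes inverse of a true charge, each with
  multiplicative noise.

What the generators do *not* emulate: polydispersity, shear-rate dependence,
concentration-dependent electroviscous effects, ion condensation dynamics,
pH drift, or correlated instrument drift.  Passing recovery tests therefore
demonstrate estimator correctness and noise propagation under idealized
instrument noise, not robustness to those real-data effects.

## Numerical choices

* Root finding: Brent on [3, 1e6], rtol 1e-13; monotonicity guarantees
  uniqueness and a valid bracket check precedes the solve.
* Line fits: numpy.polyfit with covariance for intercept standard errors;
  through-origin fits use the closed-form normal equation.
* Offset power-law fits: scipy curve_fit (LM), max 20000 evaluations,
  convergence failure raised with context.
* JSON output: sorted keys, floats rounded to 6 significant digits, so
  repeated runs on identical inputs are byte-identical.
* Degenerate inputs (identical abscissae, empty frames, non-dilute records)
  raise ValueError with a specific message or are excluded with a warning,
  as documented per function.

## Problem sizes used in checks

Statistical recovery checks use 500 seeded replicates of 10-point series;
random-walk scaling uses 10^4 frames for chains of 25–400 monomers;
stiff-chain recovery uses chains of 200–700 monomers.  These sizes give
sub-percent Monte-Carlo error on the checked medians while keeping the whole
suite interactive.

## Known limitations

* The rod model is inapplicable below lam ≈ 3 and quantitative only for
  lam ≫ 1; flexible or coiled conformations (high salt, low charge) violate
  its assumptions even when [eta] > 2.5.
* The one-step inversion degrades below [eta] ≈ 60 (see above).
* Effective-charge values are friction-model dependent; for kappa^-1
  comparable to or smaller than dH the Lorentz–Stokes estimate loses
  accuracy.
* Interpolant coefficients are grid-dependent; use the exact inversion when
  three-digit agreement matters.
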