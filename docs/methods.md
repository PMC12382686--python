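# Methods

`soilcolumn` models constant-head infiltration of water and the coupled
transport of a dissolved antibiotic (gentamicin) through a short laboratory
soil column, and calibrates the model's free parameters from the two kinds of
observation such an experiment produces: the cumulative-infiltration curve
and the end-of-test concentration-by-depth profile.

## Governing equations

**Water flow.** One-dimensional Richards equation, z positive downward (cm),
time in hours, pressure head h (cm, suction ψ = −h):

    C(ψ) ∂ψ/∂t = ∂/∂z [ K(ψ) (∂h/∂z − 1) ],      q = K (1 − ∂h/∂z)

with zero sink (no roots or evaporation in a column test). Closures:

* Retention (van Genuchten): Θ(ψ) = [1 + (ψ/ψ_d)^n]^(−m), θ = θ_r + (θ_s − θ_r)Θ.
  Shape parameters m, n are free (no Mualem/Burdine constraint); ψ_d is the
  characteristic pressure scale in cm of suction.
* Conductivity (fractal geometric-mean pore model):
  K(Θ) = K_s [1 − (1 − Θ^{1/m})^{s_m}]², with s_m = 1 − 2s/n ∈ (0, 1).
  The printed rendering of this model is typographically ambiguous; the
  reading above is the default and the alternative grouping
  K = K_s [1 − (1 − Θ^{1/s_m})^m]² is selectable (`form="fractal-alt"`).
* Relative fractal dimension from porosity: (1 − φ)^s + φ^{2s} = 1, solved by
  Newton–Raphson (start 0.7, ≤100 iterations) with a bracketed Brent
  fallback on [10⁻³, 1 − 10⁻³]. The equation is the authority: for
  φ = 0.4906 the root is s = 0.6923 (a published table prints 0.7019, which
  does not satisfy the equation at that porosity; the package asserts the
  defining relation, not the rounded table entry).
* Porosity φ = 1 − ρ_a/ρ_s; θ_s = φ and θ_r = 0 by default, both overridable.
* Grain-size CDF: F(D) = [1 + (D_d/D)^{n/(2(1−s))}]^(−m), fitted for
  (D_d, m, n) with s held fixed (s depends only on porosity), by bounded
  least squares on log-spacing-weighted residuals with a 3-point multi-start.

**Solute transport.** Advection–dispersion with a linear isotherm folded into
the storage coefficient:

    ∂[(θ + ρ_a K_d) C]/∂t + ∂(q C − θ D ∂C/∂z)/∂z = 0

θ and q come from the flow solution; the sink term is zero (no degradation on
column time scales). K_d = 0 by default — the study's working assumption is
that gentamicin stays in the liquid phase — which makes the retardation
factor R = 1 + ρ_a K_d/θ equal to one. D is a single constant effective
dispersion coefficient, as the calibration tables report; a
velocity-dependent dispersivity mode was considered and deliberately not
implemented as a default because the calibrated quantity in the source
experiments is the constant D (the printed unit label "m²/s" for D is
physically implausible for a soil column — it exceeds molecular diffusion by
seven orders of magnitude — so the values are treated as magnitudes in the
package's model units, cm²/h).

## Discretisation

Both equations are solved on the same cell-centred finite-volume grid (cells
of width Δz, Dirichlet boundaries imposed through half-cell fluxes) with
fully implicit (backward-Euler, Laasonen-type) time stepping.

* **Flow** uses the mass-conservative mixed form of the storage term
  (modified Picard: θ-based residual, C(ψ)-based Jacobian), because the
  literal C(ψ)∂ψ/∂t form loses mass on affordable grids; that literal form is
  retained behind `storage_form="c-form"` for comparison, and a test verifies
  it is the lossier of the two. A small specific storage (10⁻⁶ cm⁻¹) enters
  the Picard Jacobian only — never the residual or the mass ledger — to keep
  the matrix nonsingular when C → 0 under ponding. Inter-nodal conductivity
  is the geometric mean of nodal values (arithmetic mean selectable); the
  geometric mean behaves better at sharp wetting fronts on coarse grids.
  Picard tolerance is 10⁻⁶ cm on pressure head, ≤50 iterations, then the
  step is halved (≤5 times) before the solver raises with diagnostics.
* **Transport** uses first-order upwinding of advection inside the implicit
  scheme: unconditionally stable and positivity-preserving (the matrix is an
  M-matrix), at the price of numerical dispersion of order v·Δz/2, which is
  quantified against the Ogata–Banks analytical solution (< 1% L2 at
  Δz = 0.005 cm under steady flow). A grid-Peclet warning fires when
  v Δz/D > 10. The inlet condition is third-type by default (Robin, total
  flux continuity q·C_in), with Dirichlet selectable — Dirichlet inlets are
  known to underestimate concentration profiles in this setting. The outlet
  has zero dispersive gradient.
* **Coupling.** The flow solver stores, between consecutive saved snapshots,
  window-averaged face fluxes reconstructed so that they satisfy *discrete*
  continuity with the stored θ exactly. The transport solver steps on the
  snapshot grid using those fluxes, so a uniform concentration field is
  exactly stationary and the solute mass ledger closes to round-off even on
  a transient flow field. (Interpolating instantaneous fluxes instead would
  leak mass at the level of the snapshot truncation error.)

Time stepping ramps geometrically from Δt₀ = 10⁻⁶ h by factor 1.05 up to the
ceiling Δt (the early ponding transient is stiff: the surface cell jumps from
ψ ≈ 1400 cm to the ponded head instantly). Steps land exactly on snapshot
times. The solver default ceiling is 10⁻⁴ h; the calibration workflows use
2×10⁻³ h with Δz = 0.05 cm, a deliberate desk-scale choice — halving Δz and
Δt changes the cumulative infiltration by < 1%, which is the package's
grid-convergence criterion, so the coarser grid is adequate and the inverse
problems stay interactive. Reference-scale increments (Δz = 0.001 cm,
Δt = 5×10⁻⁶ h) are accepted but give the same answers far more slowly.

## Boundary and initial conditions

Upper boundary: Dirichlet ponded head h = +3.5 cm (water depth maintained on
the surface). Lower boundary default: free drainage (unit gradient), matching
a column draining through a porous plate to a funnel; a fixed-suction option
(e.g. ψ = 0, a water table at the base — this is the configuration whose
steady state is the textbook Darcy flux K_s(h + L)/L) and a simplified
seepage face are also provided. Initial condition: uniform volumetric
moisture; the laboratory initial moisture was measured but never published,
so the package default is θ_i = 0.10 cm³/cm³ and every run configuration
echoes the value it used to the log.

Because θ_i is unknown, the published saturation times (274 min for pure
gentamicin, 59 min for the sulfate) are not reproducible quantitatively.
They are not reproducible qualitatively either, at *equal* initial moisture:
the capillary drive of the pure-gentamicin calibration (K_s ψ_d ≈ 88 cm²/h)
exceeds the sulfate one (≈ 69 cm²/h), so the model saturates the c1 column
slightly sooner when both start equally dry. The experimental ordering
presumably reflects different initial moistures in the two physical columns.
The package therefore tests the defensible monotonicity (wetter initial
state ⇒ earlier saturation) and leaves the cross-case ordering alone.

## Inverse estimation

Two-stage, mirroring the experimental analysis: first (K_s, ψ_d) from the
cumulative-infiltration curve with the retention shape (m, n, s) fixed, then
D from the depth profile on the frozen flow field.

* Both estimators follow the scikit-learn protocol. The infiltration stage
  is bounded least squares (scipy `trf`, the bounded Levenberg–Marquardt-type
  method) on log10-transformed parameters with Jacobian-based scaling and a
  relative finite-difference step of 10⁻³ in log space — the (K_s, ψ_d)
  objective is a curved, badly conditioned valley, and smaller difference
  steps stall the optimiser short of the minimum. Default bounds:
  K_s ∈ [10⁻³, 10²] cm/h, ψ_d ∈ [1, 10³] cm, D ∈ [10⁻⁶, 10] cm²/h.
  A deterministic 3-point multi-start over the initial guess is the
  estimator default; single-start runs from a generic template are used
  where the data are noise-free and the extra starts only repeat the answer.
* The dispersion stage is a one-dimensional search on log10 D: a 25-point
  grid scan between the bounds followed by bounded scalar minimisation in
  the bracketing interval (tolerance 10⁻⁵ on log10 D). A profile with equal
  concentrations at all depths carries no information about D; that
  degenerate input is flagged (warning + `converged=False`), never silently
  fitted.
* Goodness of fit is reported as RMSE and R² (R² about the observed mean;
  zero observed variance returns NaN as the undefined sentinel). The running
  best objective value is recorded per evaluation (`objective_trace`).
* Generation and refitting always share one grid, so recovery tolerances
  measure the estimator, not discretisation mismatch.

Identifiability caveat: the infiltration curve constrains ψ_d through the
early, sorptivity-dominated phase and K_s through the late quasi-steady
phase. Observation windows that end before the steady phase leave K_s poorly
identified under noise — the noisy-recovery test uses a half-hour window for
exactly this reason.

## Synthetic data

The generator stands in for the unpublished raw measurements. It runs the
forward model at stated truth parameters and emits:

* cumulative-infiltration readings thinned to a 2-minute cadence (a
  realistic manual reading interval);
* depth profiles at 1/3/5/7 cm, by default at the simulated saturation time
  (the moment the real columns were sectioned);
* grain-size curves from the fractal CDF;
* absorbance readings from the spectrophotometric calibration line
  A = 0.0009·C + 0.0992 (C in mg/L), inverted exactly on the way back.

Noise models: none, additive Gaussian, multiplicative Gaussian. Defaults
when noise is requested: multiplicative σ = 5% for infiltration (volumetric
readings scale with the signal) and additive σ = 2 mg/L for concentrations
(assay-limited); the source experiments report no error model, so these are
plausible laboratory scales chosen once. Generators are pure functions of
(truth, seed) and bit-reproducible.

What the synthetic data do **not** emulate: spatial heterogeneity, wall
effects, extraction-efficiency losses of the soil assay, spectrophotometer
drift, hysteresis, air entrapment. Passing recovery tests therefore show
that the inverse machinery is correct and well-posed on data the model can
represent — not that the model captures every feature of the laboratory
system.

## Management scenarios

Two presets per solute, as in the source study: *continuous* application
(2000 min pure / 360 min sulfate) and *flushing* — solute applied until the
column saturates, then clean water (720 min pure / 180 min sulfate). The
flush schedule switches the inlet concentration to zero; stored solute mass
is then non-increasing, which is asserted as a property.

## Numerical edge cases and tie-breaks

* Suction is stored as a positive magnitude; ponded states are negative
  suction and saturate the retention curve (Θ = 1, C = 0).
* Saturated cells keep the flux terms in the Jacobian diagonal, so the
  implicit matrix stays nonsingular even with C = 0 everywhere.
* Transport concentrations more negative than 10⁻¹²·C0 abort the run;
  smaller undershoots (pure round-off) are clipped to zero.
* `time_to_saturation` uses min-over-depth θ ≥ θ_s − tol (tol = 10⁻³ by
  default) on stored snapshots and returns `inf` when never reached.
* Zero bulk density and fully dense soil are accepted as the trivial
  porosity limits 1 and 0; bulk density above particle density is an error.

## Known limitations

One-dimensional, single solute, rigid matrix; no hysteresis, air phase,
biodegradation, or Freundlich/Langmuir sorption. The printed-unit
reconciliation for D (above) means absolute dispersion values are
model-unit magnitudes; ratios between solutes, which is what the study's
conclusions rest on, are unit-free. RMSE values published for the laboratory
fits are not reproducible because the underlying observations exist only as
figures.
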