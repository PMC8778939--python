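# Methods

This note records the model as implemented, the parameters that matter and
where their defaults come from, the numerical choices, and the limitations
a user should know before trusting a number.

## Geometry and discretization

The domain is three nested spheres: the MNP injection site (radius
0.25 cm), the tumor (1 cm) and surrounding normal tissue (3 cm). All
fields are spherically symmetric, so the solvers work on a 1-D radial
finite-volume grid (node-centered; control-volume faces midway between
nodes; region interfaces exactly on nodes). Region-restricted integrals
weight each control volume by its exact geometric overlap with the region
shell, so region volumes and deposited doses are independent of
resolution. Default mesh: 20 / 80 / 60 nodes per region with tanh
refinement toward the interfaces (161 nodes total). The steady
conduction–perfusion solver converges at second order against the
screened-Poisson closed form (verified in the test suite); 161 nodes put
the discretization error well below every tolerance used here.

A 2-D axisymmetric finite-element treatment of the same geometry resolves
the identical physics; the 1-D reduction is exact for this configuration
up to discretization, and its one real consequence for the calibration is
discussed under *Thermal calibration*.

## Magnetic heating

Single-domain magnetite particles (d = 10 nm, volume fraction 3.3 % in
the injected ferrofluid) under a 400 kHz alternating field dissipate by
Néel/Brown relaxation in the linear-response regime:
Q = φ μ₀ χ₀ H²f · x/(1+x²), x = 2πfτ_eff. Choices:

* **τ_N form.** The Rosensweig form (√π/2) τ₀ e^Γ/√Γ is the default; a
  `literal` variant π τ₀ e^Γ/(2Γ) is config-selectable. At the calibrated
  Γ ≈ 5 the two differ by ~25 %, which the K_eff calibration absorbs.
* **χ₀.** Chord (Langevin) susceptibility per unit particle volume, so the
  explicit φ in Q is applied exactly once. M_d = 446 kA/m (magnetite),
  τ₀ = 10⁻⁹ s, δ = 10⁻³ Pa·s, no coating — standard values, all exposed.
* **No extra π prefactor** in Q by default; a `rosensweig_pi` switch
  inserts the textbook π for sensitivity studies.
* **Evaluation temperature.** Q is evaluated at 37 °C and held constant
  during the exposure. The relaxation times' drift over a 7 °C rise is a
  few percent — second order next to the K_eff calibration — and a constant
  source keeps the heating stage linear and bit-reproducible.

## Bioheat and thermal kill

Pennes bioheat with temperature-independent properties and
non-temperature-modulated perfusion (a deliberate model exclusion),
implicit (backward Euler) fixed steps of 0.001 h, Dirichlet 37 °C at the
outer boundary, symmetry at r = 0. Basal metabolic heat is folded into the
37 °C reference equilibrium (`metabolic_heat` defaults to 0; a uniform
37 °C field with no MNP source is then exactly stationary, which the
maximum-principle test asserts). Arrhenius damage
(A = 1.98·10¹⁰⁶ s⁻¹, ΔE = 6.67·10⁵ J/mol) is accumulated by trapezoid
over the stored history, through heating and cool-down until the peak
temperature falls below 37.5 °C.

### Thermal calibration

The anisotropy constant K_eff, the spatial extent of the deposited MNPs
and the perfusion rates are not tabulated anywhere; they are calibrated
(`scripts/calibrate.py`) against the reference 60-min exposure at
400 kHz / 11 kA/m: 42.2 °C at the depot center and ≈38.5 °C at the tumor
border. Two structural facts force the calibration's shape:

* With a sharp 0.25 cm source sphere, pure conduction bounds the
  border-to-surface temperature-rise ratio by
  (1/r − 1/R)/(1/a − 1/R) ≈ 0.18 (perfusion only lowers it), so a 5.2 °C
  center rise cannot produce more than ~1 °C at the border — the reference
  temperature pair is unreachable no matter the parameters. Injected ferrofluid does
  not stay in a perfect sphere, however: the model therefore deposits the
  (conserved) MNP dose over an **effective deposition radius**, default
  0.5 cm = 2× the injection radius — consistent with the observed release
  zone extending to twice the injection radius. The in-zone volume
  fraction scales down by the cube of the radius ratio (to 0.41 %).
* The depot's effective thermal conductivity uses the **arithmetic
  (parallel) mixing bound** by default, representing aggregated/chained
  magnetite deposits; Maxwell–Garnett (isolated dilute spheres) is the
  config alternative. With Maxwell–Garnett the intra-depot gradient eats
  the border temperature for any plausible deposition radius.

With deposition radius 0.5 cm, tumor perfusion 10⁻⁴ s⁻¹ (hypoperfused
core; normal tissue 5·10⁻⁴ s⁻¹, ρ_bC_b = 3.6·10⁶ J/m³K), the K_eff root
find gives **4.39·10⁴ J/m³** — inside the usual 2–10·10⁴ J/m³ range for
magnetite nanoparticles. The resulting steady field: 42.20 / 38.67 °C at
11 kA/m (center/border), 44.2 / 39.3 °C at 13 kA/m; tumor-averaged heat
kill at 13 kA/m ≈ 12 %. The center plateaus (99 % of steady rise) after
~27 min. That the 13 kA/m field holds the *entire* tumor above 39 °C is
what lets the liposomes release tumor-wide (below).

## Interstitial fluid

Darcy flow with Starling filtration toward the effective head
p_e = P_b − σ_s(π_B − π_i) = 11.5 mmHg inside the tumor (no lymphatics
there), solved once at steady state and frozen. Normal tissue defaults to
**lymphatic-dominated drainage toward zero pressure**: its vasculature
filters, its lymphatics drain, and the net effect is a screened sink at
p ≈ 0. This reproduces the canonical profile — an 11.5 mmHg core plateau,
≈3.5 mmHg at the tumor border, near-zero just outside, and an outward rim
velocity of ~0.12 µm/s. A `net_zero` closure (no exchange in normal
tissue) is available but throttles tumor efflux through 2 cm of passive
tissue, holding the border at ~11 mmHg and the rim velocity two orders of
magnitude lower; it is not the default for that reason.

## Drug transport

Four compartments (liposomal, free, bound, internalized doxorubicin) with
the tabulated kinetics: D_F = 3.4·10⁻⁶ cm²/s, P_free = 3·10⁻⁴ cm/s,
K_ON·C_rec = 0.015 s⁻¹, K_OFF = 8·10⁻³ s⁻¹, K_INT = 5·10⁻⁵ s⁻¹,
φ_acc = 0.3 (the 1/φ factor applied symmetrically to the on- and
off-binding terms). Release is zero below 39 °C, ramps linearly to the
measured 0.05409 s⁻¹ at 42 °C and plateaus above. Because
K_EL·(60 min) ≫ 1 even at a few percent of the plateau, release within the
heated hour is effectively all-or-nothing at the 39 °C contour — the
release-zone *extent*, i.e. the temperature field, controls delivery far
more than the ramp shape (an exponential ramp variant exists and barely
changes outcomes). In TSL mode the free drug has no transvascular pathway
(the carrier crossed the wall; the cargo stays); in chemotherapy mode the
free drug exchanges with plasma everywhere, which is the side-effect
route.

Liposome wall transport comes from a hindered-pore closure: Renkin
diffusive hindrance and a (1−(1−λ)²)² reflection per pore, averaged
(pore-area weighted) over a lognormal pore-diameter distribution with
median equal to the nominal pore size. The distribution is what keeps a
100 nm carrier in a "100 nm pore" tumor partially permeable (the low-permeability
tumor case) instead of step-function blocked, and it shuts off
extravasation in normal tissue (12 nm median) completely on the 72 h
scale.

### Transport calibration and its one honest compromise

Three constants are not tabulated anywhere and are calibrated against the combination
scenario: the TSL plasma decay **kd = 30 h**, the wall permeability scale
**2.6·10⁻⁸ m/s** (times the hindrance factor ≈ 0.39 at 200 nm pores gives
P_tsl ≈ 1.0·10⁻⁸ m/s), and the pore-size geometric SD **2.0**. The
free-Dox decay **kd = 2.3 h** is fixed separately by the
conventional-chemotherapy internalized peak (0.78 mol/m³ → model 0.78,
kill 40 %); doxorubicin's terminal elimination is indeed hours-scale even
though its distribution phase is minutes.

Under this model family (mono-exponential plasma bolus, linear Patlak
exchange, filtration confined to the rim where the IFP plateau collapses),
the tumor-mean liposome concentration cannot *both* peak 9 h
post-injection *and* deliver ≈1.2 mol/m³ of internalized drug: a 9-h peak
requires slow wall exchange, which caps the interior liposome pool near
0.65 of the plasma dose. The calibration resolves the conflict in favor of
the delivered-dose and kill observables — CI peak 1.08 mol/m³, drug kill
0.51 (9 h delay), 0.21 (48 h), 0.42 (100 nm pores), 0.66 (1.5× dose),
combined kill 0.56 — and accepts a tumor-TSL peak at ~4 h. The qualitative
schedule conclusion (inject, wait for accumulation, then heat; efficacy
falls monotonically for delays past the peak) is unaffected.

## Pharmacodynamics

Drug kill 1 − exp(−ω C_I), ω = 0.6603 m³/mol, applied *locally* and then
volume-averaged over the tumor; by Jensen's inequality this is never
larger than the kill evaluated at the mean concentration, and both
conventions are reported. Heat and drug combine as independent survival
probabilities S = DS·e^(−ωC_I) — the rule that makes per-mechanism and
combined percentages consistent — with the terminal decomposition
(heat-attributable extra kill, drug kill, survivors) summing to one.

## Numerics and problem sizes

Operator splitting per transport step: (1) implicit local
reaction/exchange — the liposome equation is scalar-implicit, free/bound a
2×2 solve, internalized an update; (2) implicit upwind
advection–diffusion per mobile species (prefactored tridiagonal solves).
Default steps: 0.001 h for bioheat, 18 s for transport outside the AMF
window and 3.6 s inside it; checkpoints every 0.1 h. A 72 h combination
run takes a few seconds on one core; the step-halving test bounds the
splitting error on the terminal internalized dose below 1 %. Audits run on
every trajectory: drug mass balance (total moles vs cumulative
transvascular influx minus boundary outflux) drifts < 0.05 % and errors
out beyond 0.5 %; the steady thermal energy audit closes to round-off;
fluid mass balance closes to < 0.1 % of gross filtration. Negative
concentrations cannot arise from the scheme (M-matrix structure) and are
trapped as hard errors anyway. Everything is deterministic; the
`--seed` accepted by the scripts exists for interface uniformity.

## What the scenarios do and do not emulate

The presets are idealized study conditions, not patient predictions:
perfectly spherical geometry and deposition, homogeneous tissue blocks, a
monodisperse particle population, mono-exponential plasma kinetics, no
temperature dependence of perfusion or vascular permeability (both would
*help* delivery in vivo), no drug resistance, regrowth, or necrotic-core
heterogeneity. Passing tests show the solvers reproduce this model's
physics and its reference observables — not that a real tumor will respond
at these percentages.

## Known limitations

* The border temperature at 11 kA/m lands at 38.67 °C against the 38.5 °C
  reference — the residual of the 1-D sharp-interface reduction after the
  deposition-radius calibration.
* The 13 kA/m exposures sit at H·f = 5.2·10⁹ A m⁻¹s⁻¹, above the usual
  5·10⁹ clinical comfort bound; those presets raise the configured limit
  explicitly rather than silently.
* The tumor-TSL accumulation peak falls at ~4 h rather than the reported
  9 h (see *Transport calibration*).
* The chemotherapy bound-drug peak is ~1.9 mol/m³ per unit plasma dose;
  receptor-binding parameters as tabulated cannot produce a substantially
  larger transient regardless of closure choices.
* Heat-only kill at 13 kA/m averages ~12 % against the reported ~15 %;
  the Arrhenius constants are fixed, so this follows directly from the
  calibrated temperature field.
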