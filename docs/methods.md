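# Methods

This note documents the models, numerical choices and limitations of the
`ionpairing` package.  All concentrations are molar (mol dm⁻³), all
equilibrium constants are concentration quotients on the molar scale,
activity coefficients are taken as unity (experiments of this kind are run
at constant ionic strength, and the effect of small ionic-strength changes
on activity coefficients is neglected), and the temperature is fixed at
298.15 K with R = 8.314 J mol⁻¹ K⁻¹ for every K ↔ ΔrG° conversion.

## Speciation model

A chemical system is a set of components, soluble species with cumulative
formation constants β (so [species] = β·Π[component]^ν), and solid phases
with solubility products K_s.  A valid equilibrium state satisfies, for
every component, the mass balance

    Σᵢ νᵢⱼ cᵢ + Σₛ νₛⱼ nₛ = Tⱼ

and, for every solid, the saturation complementarity: either the solid is
absent and its ion product is at most K_s, or it is present (nₛ > 0) and
the ion product equals K_s.

**Solver.** Unknowns are x = ln[free] plus the amounts of the currently
active solids.  Residuals are relative mass-balance errors and, for active
solids, log-saturation errors; a damped Newton iteration (step halving on
the residual norm, step cap of 50 ln-units, 200 iterations) is run from
three canonical starts — all-free, strongly bound (free = totals·10⁻⁶),
and uniform 10⁻⁷ — because the formation constants span more than ten
orders of magnitude across the studied systems (β up to 10⁶·⁷ for cation
binding, K_s down to 10⁻¹³·⁷).  Convergence requires a residual ∞-norm
below 10⁻¹².  Solids are handled by an active set: solve without solids,
activate the most supersaturated solid, re-solve with its ion product
pinned, and drop any solid whose amount turns negative; with at most two
solids per system this settles in a few cycles.  Zero-total components are
eliminated analytically (their free concentration is exactly zero).

**Oracle.** `oracle_solve_1d` solves the same problem by scanning the
first component's free concentration on a 4000-point log grid (20 decades
up to ten times the total) and bisecting the bracketed sign change, with
the remaining components eliminated in closed form; it requires the model
to be triangular (each later component linear in itself given the earlier
ones).  It shares no code path with the Newton solver and is used purely
for cross-validation; the test suite requires agreement to better than
10⁻⁶ relative on hundreds of random systems.

## Salt models and fitting methods

For a 1:1 salt with ion pairing, the pure saturated solution obeys
s = √K_s + K_s·K_IP; the K_s·K_IP term is the (concentration-independent)
ion-pair contribution.  With added common anion at analytical
concentration c, s(c) = ½(2K_sK_IP − c + √(c² + 4K_s)).  In a homogeneous
solution the free cation follows from the pairing quadratic, evaluated in
a cancellation-safe form (the root is computed as 2c_C/(b + √(b² + 4K_IP
c_C)), and the analytic K_IP → 0 limit is taken when K_IP·(c_C + c_A) <
10⁻¹⁰).  With the solid present the ion pair cancels from the
cation–anion mass-balance difference and [C⁺] = ½(Δ + √(Δ² + 4K_s)) with
Δ = c_C − c_A.

For a dimerizing anion the saturated mass balance reduces to a cubic in
the free cation concentration x = s − K_s·K_IP:

    x³ + c·x² − K_s·x − 2·K_dim·K_s² = 0,

which has exactly one positive root (single sign change), bracketed and
solved by Brent's method; at K_dim = 0 the cubic factors and the ionic
quadratic is used directly.  The saturated free-cation sextic
64K_dim²x⁶ − 256K_s²K_dim³x³ − 64K_s²K_dim²x² + 256K_s⁴K_dim⁴ = 0 factors
into two cubics, and the *smaller* positive root belongs to the unphysical
factor (it implies a negative analytical co-ion concentration); the
physical root is therefore selected by mass-balance consistency
(minimizing |K_s/x + 2K_dim(K_s/x)² − x|), not by magnitude.

Four fitters wrap these forms, all optimizing in log₁₀-parameter space
(which serves the same conditioning purpose as rescaling very small
parameters, without unit juggling), with asymptotic standard errors from
the Jacobian:

* **method A** — least squares of measured solubilities vs. co-ion
  concentration; estimates (K_s, K_IP).
* **method B** — pNa titration crossing the precipitation onset; rows are
  auto-labeled by regime (solid iff the hypothetical homogeneous ion
  product strictly exceeds K_s — a state exactly at saturation counts as
  homogeneous) or use supplied labels; estimates (s, K_s), K_IP following
  from s = √K_s + K_sK_IP.  s may be frozen for titrations that
  precipitate from the first addition.  Ion pairing cancels from the
  solid-regime balance, so s is informed only by pre-onset points — the
  default synthetic design therefore samples the pre-onset region finely.
* **method E** — method A with the dimerization cubic; K_dim is a fixed
  input (its value is a literature quantity with no default; the synthetic
  preset defaults it to 10² mol⁻¹ dm³ with a warning).
* **method F** — pNa titration of the dimerizing salt with s and K_dim
  fixed; K_s is fitted on pNa residuals computed from full speciation,
  weighted by the local sensitivity |∂pNa/∂log₁₀K_s| (normalized,
  re-evaluated for up to three reweighting sweeps), which concentrates the
  fit on the region of the curve that actually responds to K_s; a
  unit-weight vector reduces the procedure to ordinary least squares.
  K_IP then follows from the pure saturated solution via
  K_IP = (s − [C⁺]_sat)/K_s.

The flame-AES helper converts a photometer reading to solubility treating
ppm as mg of analyte per kg of solution and the diluent mass as the
solution mass (appropriate for the gram-scale aqueous take-up used).

**Conditioning caveat.** At dihydrogen-phosphate-like constants
(K_s ≈ 10⁻¹³·⁷, K_IP ≈ 10⁸) the ion-pair term contributes ~95 % of the
total solubility, so method E determines the product K_s·K_IP well but
K_s itself only from a few-percent signal; under realistic noise K_s is
then essentially unidentified (the two-regime potentiometric route, method
F, is the robust alternative — consistent with which method this class of
study actually relies on).  Noisy-recovery tests for method E therefore
use a well-conditioned dimerizing system (K_s = 10⁻⁸, K_IP = 10⁴); the
phosphate-preset recovery is exercised noise-free.

## Titration observables

`TitrationSchedule` tracks dilution exactly: totals after the k-th
addition are (V₀c₀ + V_add·c_titrant)/(V₀ + V_add).

* **Potentiometry**: E = E₀ + slope·log₁₀[C⁺]; the calibration line is an
  ordinary least-squares fit of measured E vs. log₁₀ c over the standards,
  with the slope free (electrodes are sub-Nernstian in acetonitrile, so no
  59.16 mV/decade assumption is imposed).
* **Conductometry**: κ = 10⁻³ Σ λᵢcᵢ (λ in S cm² mol⁻¹, κ in S cm⁻¹);
  neutral species contribute nothing, and a charged species without a λ
  entry is an error.  No Onsager-type concentration corrections are
  applied, consistent with the unit-activity assumption; this is a
  documented limitation, acceptable at the ≤ m mol dm⁻³ working range.
* **ITC**: the cell is a constant-volume perfusion cell — each injection
  mixes into the cell and expels an equal volume of the mixed contents.
  Heats are computed from a closed-system mole ledger (cell + expelled
  liquid − injected syringe material), so per-injection heats sum exactly
  to the enthalpy-content difference between final and initial states; a
  constant per-injection dilution-heat baseline is configurable (the
  blank-titration correction).
* **UV**: Beer–Lambert additivity over the wavelength grid; isosbestic
  behavior emerges for two-state systems once absorbances are
  dilution-corrected.
* **NMR (fast exchange)**: δ_obs is the population-weighted mean shift over
  the fast-exchanging species holding the observed nucleus pool,
  renormalized within the fast pool by default (the standard approximation
  when a slow equilibrium sequesters part of the pool, e.g. a cation
  complex that is slow on the shift timescale while anion binding is
  fast); in strict mode an incomplete fast pool is an error.  Slow species
  are reported as separate signal tracks with population-proportional
  intensities; no lineshape model is attempted.

## Binding-model ladder and fitting

The ladder compares three nested treatments of the same titration:
M1 treats the cation-loaded host as an inseparable pseudo-component CH
with ion pairing ignored; M2 makes CH⁺ formation explicit but still
ignores pairing; M3 is the full model (plus anion dimerization where
defined).  A defining detail of the M1 analysis, implemented here
deliberately: the titrand's response (apparent spectrum or shift of "CH")
is frozen from the *observed initial point* of the titration — which is
all an analyst treating the titrand as one species has — rather than from
the true pure-species response.  With the true CH⁺ spectrum (information
an experimenter does not possess) the simulated M1 bias reverses sign;
with the faithful initial-point treatment the inseparable model inflates
the ternary constant for weakly pairing chloride-like systems, while
omitting ion pairing deflates it for strongly pairing hydrogensulfate-like
systems.  The magnitudes of these biases depend on the spectra and the
injection schedule; only the directions are asserted by the tests.

Fits are weighted least squares (unit weights by default) over the
appropriate forward model.  Nonlinear parameters (log₁₀ K) use multistart:
a seeded Latin-hypercube of eight starts within ±3 log units of the
heuristic start.  Response coefficients that enter linearly — molar
absorptivities, reaction enthalpies, chemical shifts, molar conductivities
— are projected out by an exact linear solve at each iterate (variable
projection), the same treatment used by standard equilibrium-refinement
software; frozen responses are honored.  Standard errors are linearized
(Jacobian at the optimum); a condition number above 10¹² on JᵀJ flags a
near-flat likelihood direction in the fit message rather than silently
clipping.  Cooperativity is reported as α = K(ternary, successive)/
K(binary anion), with the thermodynamic-cycle identity
log K(CH⁺) + log K(CHA|succ) = log K(HA⁻) + log K(CHA|anion-first)
available as a consistency check.

**Preload design check.** For very stable cation complexes (c·K ≈ 10³)
the ITC isotherm is nearly rectangular.  Under idealized white heat-noise
with exactly known concentrations, a conventional titration is *not* less
precise than one starting at 0.8 cation equivalents — the corner point
and long plateau over-determine everything.  The practical advantage of
preloading emerges once the dominant replicate-level systematic of this
calorimetry is modeled: the active titrand concentration (purity,
weighing, residual solvent) is uncertain at the percent level while fits
use the nominal value.  `itc_design_check` therefore simulates each
replicate with Gaussian heat noise (1 µJ) *and* a 2 % relative titrand
concentration error, fits at the nominal concentration, and compares
empirical standard errors of log K between designs of equal effort (same
injection count, same final equivalents, titrant concentration adjusted).
Under this model preloading clearly reduces the standard error at
log K ≈ 6.7 and offers no benefit at log K ≈ 3, reproducing the rationale
for the design.

## Synthetic data

Generators cover every experiment type (solubility series, two-regime pNa
titrations, conductometric and calorimetric titrations including the
0.8-equivalent preload variant, multiwavelength UV, fast-exchange NMR) by
running the corresponding forward model at a named preset and adding
seeded Gaussian noise; zero noise reproduces the forward model bitwise,
and the metadata sidecar (truth, noise, schedule, seed) suffices to
regenerate any dataset identically.

Preset constants: NaCl-like (log K_s = −8.7; K_IP = 7.7 × 10³ as an
explicit placeholder for a table-only value, warned about when defaulted),
NaHSO₄-like (K_s = 2.6 × 10⁻⁸, K_IP = 3.6 × 10⁴ from the calorimetric
ΔrH° = −7 and −TΔrS° = −19 kJ mol⁻¹), NaH₂PO₄-like (−log K_s = 13.7;
K_IP ≈ 1.4 × 10⁸ chosen so the pure solubility is twenty-fold below the
NaCl value, keeping the documented K_IP/K_s compensation; K_dim is a
required literature input defaulted to 10² with a warning).  Host
constants: log K(CH⁺) = 6.69, log K(CHA) = 3.27 with the binary chloride
constant one decade lower, log K for the hydrogensulfate ternary 2.45 with
the binary constant five-fold lower.  Every preset satisfies
s = √K_s + K_s·K_IP exactly.

Default noise levels are typical instrument precisions: 0.01 pNa units,
0.2 % relative conductivity, 1 µJ per injection, 0.002 absorbance units,
0.002 ppm, 2 % relative solubility.  Default schedules are plausible
reconstructions of the stated protocols (e.g. UV: 25 × 20 µL of 5 m mol
dm⁻³ titrant into 2.2 mL of 2 × 10⁻⁴ mol dm⁻³ 1:1 host/cation solution —
about 2.9 equivalents, within cuvette capacity; pNa: 30 × 5 µL of 10⁻²
mol dm⁻³ titrant into 25 mL, sampling the pre-onset region finely);
problem sizes throughout (20–30 titration points, ≤ 10³ random systems,
50 Monte-Carlo replicates, a few hundred frames) are chosen so the whole
battery runs in about a minute on one core while leaving estimator noise
well below the asserted tolerances.

The canonical UV spectra are a hyperchromic, slightly red-shifting
Gaussian family (complexation raises the aryl-band intensity, most for the
ternary complex; anions are transparent in the window), and the NMR shift
set moves the urea-NH resonances downfield on anion binding — both
qualitative signatures of this host class.  What passing tests on such
data do *not* show: recovery of the study's experimental constants from
its raw data (not deposited), real spectral shapes, activity effects,
precipitation kinetics (the phosphate salt precipitates slowly; all solid
handling here is equilibrium), or electrode drift.

**Frame generator.** Idealized host/ion geometries realize requested
coordination signatures: four ether and two amide oxygens around the
cation site, two urea groups flanking the anion site, a cavity cylinder
defined by four narrow-rim reference atoms and four wide-rim atoms, and
one acetonitrile molecule placed methyl-end-in, nitrile-end-in or outside.
Contact distances sit ≥ 0.6 Å inside the classification cutoffs and
non-contacts ≥ 0.6 Å outside, so a 0.2 Å Gaussian jitter retains the
signature in ≳ 95 % of frames; geometrically impossible signatures (more
than two NH per urea, more donors than the four NH groups, Na totals not
equal to ether + amide parts) are rejected.

## Coordination analysis

Criteria are applied literally with strict inequalities: Na–O contacts at
d < 3.0 Å with the C–O–Na angle in the open interval (0°, 180°) — a
window that only excludes exactly collinear or degenerate geometries, and
is implemented as stated rather than tightened; Cl contacts at
d(H···Cl) < 2.9 Å with N–H–Cl in (90°, 180°); intramolecular hydrogen
bonds at d(H···O) < 3.2 Å with N–H–O in (90°, 180°).  N–H and C–O
connectivity always comes from labeled bonds, never from distance
heuristics.  The Na matrix is (total, ether, amide); urea oxygens are
screened and would enter the total, though no canonical structure has
them coordinate.  Solvent inclusion tests which acetonitrile end lies
inside the cavity cylinder (radius 2.5 Å about the axis from the
narrow-rim centroid to the wide-rim centroid, between the two rim planes);
if both ends are inside, the deeper one decides.

Frames are grouped by their discrete signature — signatures, not distances,
define cluster identity.  PCA (scikit-learn) over rigid-motion- and
atom-order-invariant feature vectors (blocks of sorted NH···O, Cl···NH and
Na···O distances followed by the matching angles; absent-ion blocks are
absent, so PCA is per system type) serves only to pick each cluster's
representative: the member frame closest to the cluster centroid in the
first three principal components.  Populations are frame-count fractions
of the ensemble and sum to 100 %.

## Known limitations

No activity-coefficient or temperature models; no precipitation kinetics;
no NMR lineshape/exchange-rate fitting; no turbidity optics (the onset is
the first solid-positive point); conductivity without relaxation
corrections; method A error propagation from the ISE calibration is not
carried into the fits.  The model-ladder bias magnitudes are design- and
response-dependent and are reported, not asserted.
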