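# Methods

This note documents the models implemented in `stalkscreen`, the
choices made where the design was genuinely open, and what the
synthetic-data generators do and do not emulate.

## Stalk geometry

A stalk is treated as a conical frustum: height `H`, base radius `R`,
top radius `r` (all cm, radii halved from field-sheet diameters at
ingest).  The whole-stalk volume is `V_WS = πH/3·(r² + rR + R²)`.  A
sampled internode occupying `[H_B, H_B + L_SI]` along the stalk has end
radii given by the linear taper `R(h) = R − h(R−r)/H`, and its volume is
the frustum formula on that segment.  These closed forms equal the
integral of `πR(h)²` exactly; the test suite checks this against
numerical quadrature and checks that volumes of contiguous segments add
up to the whole.

Extrapolation from internode to whole stalk divides by
`V_ratio = V_SI/V_WS` and by a per-analyte fixed internode-to-whole-stalk
ratio.  **Extensive** quantities (fresh weight, dry weight, sugar mass)
are divided by both; **intensive** quantities (concentrations,
digestibility rates) are divided by the fixed ratio only — this is the
only assignment that keeps units consistent, and the extensive flag is
declared per analyte in the ratio table.  The shipped default table
(FW 0.91, DW 1.00, sucrose 0.97, glucose 1.05, fructose 0.97,
digestibility 1.29, SEs 0.02–0.05) is appropriate for fourth-internode
sampling of mature sweet sorghum and must be re-estimated for other
species or sampling schemes; `estimate_fixed_ratios` does this from a
paired internode/whole-stalk table, reporting the ratio, its standard
error, the Pearson correlation and RMSEP%.  Inverted tapers (`R < r`)
are rejected as geometry errors.

## Spectral pretreatment

Spectra live on strictly monotone wavenumber grids stored in
descending (instrument) order; truncation bounds are inclusive at both
ends, so 1,180–900 cm⁻¹ on a 4 cm⁻¹ grid retains 71 points.

* **Savitzky–Golay**: polynomial order defaults to 2 (the classical
  quadratic window) for both smoothing and second derivatives; the
  order is recorded in the recipe so it is auditable.  Output is
  trimmed to interior points where the full window fits — no fabricated
  edge values enter the regression.  Derivatives are with respect to
  wavenumber (AU·cm^k), with the sign handled for descending storage.
* **EMSC**: each spectrum is regressed on a constant, linear and
  quadratic wavenumber term plus the mean calibration spectrum;
  the corrected spectrum is `(s − baseline)/b` where `b` is the
  coefficient on the reference.  The polynomial terms use wavenumber
  rescaled to [−1, 1]; this is an affine reparameterisation that
  changes nothing but conditioning.  A scatter coefficient below 1e-8
  in magnitude is a degenerate fit and is rejected.
* **Mean centering** is held inside the PLS model (`x_means`,
  `y_means`) rather than as a recipe step.

A fitted recipe is frozen: applying it never re-estimates the EMSC
reference, and it serializes inside the model JSON so a loaded model
reproduces calibration-time preprocessing bit for bit.

## PLS engine

Two algorithms produce identical models: classical **NIPALS**
(initialised from the response column of maximal variance, iteration
tolerance 1e-12, at most 500 iterations per component) and the
**wide-kernel** association-matrix variant (power iteration on the
deflated `XX'YY'` operator), suited to matrices with many more
wavenumbers than samples.  Both assemble regression coefficients as
`B = W(PᵀW)⁻¹Qᵀ` and are tested to agree to 1e-8.  One caveat: with
multiple response columns and a component count equal to the full
centred rank, the trailing components' eigenvalue gaps vanish and the
NIPALS inner iteration cannot reach its tolerance; the engine raises a
non-convergence error rather than returning an unconverged model.

"Full cross-validation" is leave-one-out: `n` refits, pooling
out-of-fold predictions to give RMSECV as a function of component
count.  Component selection takes the smallest count whose RMSECV is
within 1% of the minimum (parsimony rule; ties break toward fewer
components).  Shipped defaults for juice sugar models are 6/9/6
components for sucrose/glucose/fructose with a 15-component
cross-validation cap.

**Variable filtering** uses Martens' jackknife: coefficients are
re-estimated in every leave-one-out fold, the per-wavenumber variance
is `((n−1)/n)·Σ(b_i − b̄)²`, and a normal-approximation confidence
interval at level 1−α (default α = 0.10) is placed around the
full-data coefficient.  Wavenumbers whose interval spans zero are
removed and the model refit; removing everything is an error.

**Bias correction**: an ordinary least-squares line is fit to the
out-of-fold predicted-versus-reference pairs; the intercept is
subtracted from subsequent predictions (for juice spectra this
removes the constant water-background contribution) and a slope factor
`1/b` is applied only when the slope deviates from one by more than a
1% dead band.  Negative concentration predictions are reported and
flagged, never clamped, so error statistics stay honest.

**Diagnostics**: leverage is `1/n + t_iᵀ(TᵀT)⁻¹t_i` (leverages sum to
`n_components + 1` under this intercept convention); samples are
flagged when leverage exceeds `3(k+1)/n` or the absolute studentized
response residual exceeds 3.  Flags are advisory — removal is a
deliberate separate step, mirroring manual outlier examination.  The
limit of detection is `3.3 ×` the standard deviation of bias-corrected
predictions on at least ten blank spectra, an ICH-style convention
adopted here as one admissible definition for inverse calibration.

## Yield calculation

Sugar concentrations convert from mM to g/100 mL via molar masses
(sucrose 342.30, glucose and fructose 180.16 g·mol⁻¹).  Juice volume is
taken as whole-stalk FW − DW grams of water at density 1 g/mL, with an
optional extraction-efficiency factor for juice retained in bagasse.
Cell-wall sugar is `D × B(mg) × hours × 10⁻⁶` g, with digestion time a
parameter defaulting to 24 h, and reducing-sugar mass is counted as
fermentable sugar 1:1.  The total is the sum of the soluble and
cell-wall terms, linear in each of V, [S], B, D.

## Synthetic data

The generators are pure functions of their parameters and a seed.

* **Juice**: each sugar is a sum of 4–8 Gaussian bands in the
  870–1,160 cm⁻¹ region; three bands per sugar sit near shared anchor
  positions so every sugar pair overlaps within 30 cm⁻¹ —
  quantification genuinely requires multivariate regression, as in real
  sugar mixtures.  Water contributes one broad band near 1,635 cm⁻¹.
  Spectra follow the Beer–Lambert mixture model
  `A = water + Σ cᵢ·εᵢ + noise`, with the default noise SD set to 0.2%
  of the maximum sugar band absorbance at mid-range concentration.  The
  default calibration design is a 6×6×6 full factorial (216 mixtures)
  over 0–600 / 0–300 / 0–150 mM, ranges bracketing observed sweet
  sorghum juice.
* **Bagasse**: latent digestibility is uniform over
  0.95–12.1 μg·mgDW⁻¹·h⁻¹ (screening calibration sets are assembled to
  approach a uniform digestibility distribution), and the wall
  composition on the (cellulose, xylan, lignin) simplex is derived from
  it so digestibility is exactly affine in composition.  The three wall
  component spectra share a dominant common band core plus smaller
  component-specific bands: real bagasse spectra are dominated by a
  common lignocellulose signature, and because compositions sum to one
  the shared core cancels across samples, keeping the EMSC scatter
  coefficient nearly composition-independent.  Spectra carry
  multiplicative scatter (log-normal, σ = 0.05), an additive offset
  (σ = 0.01 AU) and spectral noise; the digestibility reference carries
  N(0, 0.3) assay noise.
* **Stalks**: heights uniform over 237–338 cm and whole-stalk fresh
  weights over 228–941 g (the observed field ranges); radii, internode
  position and length drawn subject to the geometry invariants; each
  internode measurement equals the whole-stalk truth × V_ratio (for
  extensive analytes) × fixed ratio × (1 + multiplicative noise).
  Whole-stalk truths are retained for recovery tests.

What the generators do **not** emulate: ATR penetration-depth and
instrument line-shape effects, atmospheric CO₂/water-vapour features,
band shifts with concentration or matrix, non-linear detector response,
correlated (pink) noise, real sugar/cell-wall band positions, and
biological covariance between geometry and composition.  Passing tests
therefore demonstrate the correctness and self-consistency of the
algorithms under the declared statistical model, not instrument-level
accuracy on real juice or bagasse.

## Numerical choices and degenerate inputs

Truncation requires at least two retained grid points; alignment is
linear interpolation only (monotone, bounded) and refuses to
extrapolate.  NIPALS raises on rank exhaustion or NaN input.
Cross-validation needs at least three samples.  Bias calibration needs
three pairs and a non-constant reference.  Model files are versioned
JSON; unknown versions and truncated files are rejected.  CLI exit
codes: 0 success, 2 validation error, 1 runtime error.  Yield runs skip
and report rows with invalid geometry instead of aborting the batch.

## Problem sizes

The shipped tests and the acceptance script use the study-scale
problem sizes: 216-mixture calibrations with 100-sample validation
sets for sugars, 52/38 calibration/validation bagasse sets, 1,000-stalk
populations for extrapolation statistics and 200-stalk populations for
ratio-recovery checks.  Everything runs in seconds on one CPU.

## Known limitations

* The wide-kernel route recovers weights through `W = XᵀU`, which is
  numerically adequate for the tested sizes but less stable than
  bidiagonalisation approaches for very ill-conditioned problems.
* EMSC estimates scatter per spectrum by regression on the mean
  reference; when chemical variation projects strongly onto the
  reference, part of it aliases into the scatter coefficient.  The
  bagasse generator's shared-core construction keeps this leak small by
  design; on real spectra with large composition spread an
  interferent-augmented EMSC basis would be the next step.
* The fixed-ratio table is species- and protocol-specific; shipping
  defaults are sensible for fourth-internode sweet sorghum sampling
  only.
* Juice volume from FW − DW assumes all stalk water is expressible
  juice; the extraction-efficiency factor exists precisely because this
  overestimates pressed volume.
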