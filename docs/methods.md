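# Methods

This note documents the statistical and numerical choices in `plantarmap`:
the model, its assumptions, the tunable parameters, what the synthetic data
generator emulates, and the limitations a user should keep in mind.

## Data model and preprocessing

A measurement is a video `V(x, t)` of pressures (kPa) on a sensor grid,
one stance phase per recording. Preprocessing has four steps, in order:

* **Square resampling.** Plates acquire on anisotropic grids (7.62 × 5.08 mm
  for the hardware the defaults target), compressing the foot
  anterior-posteriorly. Frames are resampled to an isotropic grid
  (`target_mm = 3`) by cubic spline interpolation (`grid_mode=True`, reflect
  boundary: constants are preserved exactly and the pressure-area integral
  of smooth fields to <1%; negative overshoot is clamped to 0).
* **Total-mean normalization.** `M(x)` is the mean of samples above the
  contact threshold τ = 5 kPa; every sample is divided by `Σ_x M(x)`. This
  removes walking-speed scaling while preserving the spatial distribution.
  The divisor is stored so thresholds stated in kPa can be mapped onto the
  dimensionless scale: silhouettes of normalized images therefore reproduce
  the raw-kPa support exactly. (Exact scale invariance holds when the
  contact set is unchanged by the scaling; loaded pixels sit far above τ in
  practice.)
* **Peak image.** `I(x) = max_t Ṽ(x, t)`.
* **Left orientation.** Right feet are mirrored across the
  anterior-posterior axis; left and right feet are treated as independent
  samples of one left-foot model. Convention: axis 0 runs heel→toes, axis 1
  lateral→medial (medial at high column index for left-oriented images).

## Registration

**Rigid stage.** Mutual information between peak images, from a 50×50 joint
histogram over the union of supports, each image binned on [0, max]. MI is
maximized with a 1+1 evolution strategy: Gaussian mutation of
(angle, translation), accept only improvements, multiply the step by 1.05
on success and 0.98 on failure; initial steps 2° / 4 mm, budget 500
iterations, convergence at 0.1° / 0.1 mm. Rotation is parameterized about
the moving image's center of pressure, and the translation starts at the
center-of-pressure difference — without that initialization most of the
budget is spent crossing a flat MI region. Measured recovery on synthetic
feet: perturbations to ±15°/±15 mm recovered within 1°/1 mm in ≥95% of
seeded trials (typically to ~0.05°/0.05 mm). If no candidate improves on
the identity, the identity is returned with a warning.

**Deformable stage.** Classical demons on the binary footprint silhouettes
(presmoothed with σ = 1 px), *not* on intensities: intensity differences
between a patient and the healthy baseline are the signal the statistics
must preserve, so only outline shape is warped. Per iteration: demons force
(difference × gradient over |∇|² + diff², step capped at 2 px), Gaussian
fluid smoothing (σ = 1.5 px), exponentiation of the update by
scaling-and-squaring (6 squarings), composition, then diffusion smoothing
of the accumulated field with σ = 1.5·√(λ₂/λ₁) px. Iterates with
non-positive Jacobian determinant are rejected; the best-SSD iterate is
returned, falling back to the identity if deformation would lower the Dice
overlap. The λ ↔ σ mapping is a modelling choice, not an identity; Dice and
minimum Jacobian are reported as QC instead of claiming equivalence.

**Within-foot averaging.** Repeated measurements of one foot are rigidly
aligned to a seeded randomly chosen reference and averaged (deformable
alignment is unnecessary within a foot, where shape is constant and only
placement varies).

## Groupwise template

Pixel statistics need an anatomically unbiased frame. The template loop:
(1) seeded random initial template; (2) register every foot onto it
(rigid + silhouette demons) and average the aligned intensities;
(3) average the inverse transforms (circular-mean angle, arithmetic-mean
translation about a common center; per-pixel mean displacement, with the
field inverse computed by fixed-point iteration); (4) apply the averaged
inverse to the mean image. Repeat until the relative L2 change is below
`tol = 1e-3` (default budget 10 iterations). Averaging intensities as well
as geometry is what makes the result initialization-insensitive: measured
two-seed disagreement is ≲0.1% on clean cohorts and <5% under ±8°/±8 mm
placements. Per-pair registration seeds are independent of the iteration
number, so registration noise is a fixed function of the template and the
loop can settle.

## Pixel-wise model

At each template-silhouette pixel: OLS of the N aligned peak pressures on
`z = [age (yr), sex (0 = female/1 = male), weight (kg), height (cm),
shoe size (EU), 1]`, solved by a stable least-squares factorization (never
explicit normal equations). Residual SD `s(x)` uses divisor N − p with
p = 6 (unbiased under the model; N − 1 available via
`variance_divisor="sample"` for literal replication of sample-variance
conventions). The model requires N > 6 and a full-rank design; collinear
columns are named in the error. Covariates enter raw (no standardization).
The residual matrix is retained for diagnostics and smoothness estimation.

Prediction for a new patient is `z_new · b(x)`, clamped at 0 (count
reported); demographics outside the training ranges warn (extrapolation)
rather than fail.

**Normality diagnostics.** Per pixel, a one-sample Kolmogorov–Smirnov test
of the N residuals against `N(0, s²(x))`, with Benjamini–Hochberg FDR at
α = 0.05 across domain pixels. Because the null parameters are estimated
from the same residuals, the test is conservative — a correctly specified
model yields essentially zero rejections, so any flagged pixels deserve
attention. Pixels with s = 0 record p = 1 and are counted as degenerate.

## Single-case statistics

The residual map is `R(x) = I'_patient(x) − I_predict(x)` on the model
domain; positive values always mean measured > predicted. Three t-variants:

* `crawford` (default): `t = R / (s·√(1 + z (ZᵀZ)⁻¹ zᵀ))`, dof = N − p.
  The leverage term prices in the uncertainty of the predicted baseline at
  the patient's design point; this is the single-case statistic with
  correct type-I behaviour.
* `naive`: `t = R/s` — anti-conservative by the leverage factor.
* `literal`: `t = R/(s/√N)` — treats one observation as a mean of N; kept
  only for sensitivity analysis, inflating t by ~√N.

**Smoothness.** Residual fields are standardized by the pixel-wise residual
sum of squares; the variance of their forward differences per axis gives
`FWHM_d = √(4 ln 2 / λ_d)` (floored at 1 px, the lattice limit). Resel
counts: R2 = area/(FWHM_x·FWHM_y), R1 = half-perimeter/FWHM, R0 = 1.

**Thresholding.** The critical t solves
`R0·ρ0(t) + R1·ρ1(t) + R2·ρ2(t) = α/2` (two-sided default; both increases
and decreases are clinically meaningful) using the standard EC densities of
a 2D t-field; the solver requires dof ≥ 3, below which the second-order
density does not decay and no finite threshold exists. Sub-threshold pixels
are zeroed; suprathreshold pixels form 8-connected signed clusters.
Stationarity of the residual field is assumed; this approximation is
disclosed in QC output rather than corrected.

**Regions and patterns.** The template silhouette is partitioned into
heel (0–31% of foot length), midfoot (31–55%), metatarsals (55–81%; the
medial 36% of each row's width is MT1), toes (81–100%) — a merged form of
conventional pedobarographic masks; all fractions configurable. A pattern
flag raises when a cluster of the required sign overlaps its region by ≥4
pixels: MT1 and midfoot patterns require increases, the other regions
accept either sign. "No abnormality" holds exactly when no flag is set.

**End-to-end analysis** (`analyze_patient`) chains preprocessing,
prediction, alignment of the patient to their prediction, residuals, t-map,
RFT threshold, and pattern classification, and reports the alignment Dice;
below 0.85 the result is flagged unreliable (severe deformities may not be
alignable to a healthy baseline, making the pixel statistics meaningless).
For images already in template space (e.g. simulated patients),
`align=False` skips registration: re-aligning an already-aligned image
introduces sub-pixel interpolation error that steep pressure gradients
amplify into spurious t-values — an inherent sensitivity of single-case SPM
worth remembering when judging borderline clusters near gradient edges.

## Synthetic data generator

The generator produces left feet as sums of anisotropic Gaussian blobs at
anatomical loci (heel, midfoot, MT1–MT5, hallux, lesser toes) plus a broad
base ridge keeping the 5 kPa footprint connected (~1100–1250 px at 3 mm).
Locus amplitudes are *linear* in the demographics deviation from a fixed
reference (age 45, sex 0.5, weight 75 kg, height 172 cm, shoe 41), so the
pixel-wise regression is exactly specified and true coefficient maps are
available in closed form. Default effect magnitudes are chosen to be
resolvable at the default study size (each nonzero effect ≳10× its OLS
standard error at N = 55, residual SD 8 kPa).

Residual noise is white noise smoothed with σ = 2 px (FWHM ≈ 4.7 px — both
realistic for upsampled pressure data and consistent with what RFT assumes)
and scaled by a pixel-wise envelope proportional to the reference pressure,
saturating at 60 kPa: variability grows with loading, vanishes off the
foot, and — because the envelope is computed from the reference field, not
the subject's — every pixel keeps one residual SD across the cohort. The
envelope also keeps the zero-clipping of pressures negligible; without it,
clipping at lightly loaded fringe pixels correlates with covariates and
visibly biases coefficients (measured: age-coefficient CI coverage dropped
to 0.82).

Cohort defaults mirror the targeted study design: 55 subjects, 24
measurements per foot at 500 Hz-class acquisition. `mode="aligned"` emits
one per-foot image (signal + one between-subject field, SD 8 kPa) — the
correctly specified input for model fitting, standing in for the per-foot
average of K repeats. `mode="repeats"` emits K images per foot under
independent rigid misalignments (±5°, ±6 mm) and within-foot noise
(SD 6 kPa) for testing the alignment stages. Abnormalities are injected as
`magnitude × s(x)` over a flat disc with a Gaussian taper, with the
ground-truth plateau mask returned.

**What the generator does not emulate:** anatomical shape variation between
subjects (all feet share one blob geometry; registration is exercised by
rigid misalignment and morphological perturbation instead), nonlinear
demographic effects, heteroscedasticity across subjects, left/right
asymmetry, and time-resolved roll-off dynamics. Passing tests therefore
demonstrate correctness of the estimators and error control under the
model's own assumptions — not robustness to shape variability or model
misspecification in real cohorts.

## Calibration and power (measured)

With the default conditions (N = 55, domain ≈ 1200 px, FWHM ≈ 4.6 px ≈ 54
resels, dof 49) the two-sided family-wise critical |t| is ≈ 4.2–4.3. The
measured null family-wise error rate over 200 simulated patients is
≈ 0.005–0.01 — conservative, as expected from the leverage factor and the
discrete lattice. Detection power for a 25-pixel MT1 overload rises steeply
with magnitude: ≈14% at +3·s, ≈50% at +4·s, ≈92% at +5·s, ≈100% at +6·s.
The floor is structural: any threshold controlling the family-wise rate at
α = 0.05 over a footprint-sized domain must exceed t ≈ 4, so signals of
+3 residual SDs cannot be detected reliably at the single-case level —
clinically salient overloads (many SDs) are what the method is built to
flag. Simulation sizes used throughout (50-trial recovery rates, 200 null
draws, 20 replicate cohorts for diagnostics, 20-foot template cohorts) were
chosen to bound Monte-Carlo error well below the decision margins they
feed.

## Numerical details and degenerate inputs

* Transforms compose in closed form; averaging re-centers all transforms
  about the mean rotation center and uses the circular mean of angles.
* Cubic warps clamp negative interpolation overshoot to 0; masks warp with
  nearest-neighbour interpolation.
* All-zero videos raise on normalization ("empty measurement"); empty
  silhouettes are rejected where a footprint is required; s(x) = 0 pixels
  give t = 0 when R = 0 and a capped, flagged t otherwise.
* Every stochastic component (reference draws, ES mutations, generator
  noise, simulations) takes an explicit seed; identical seeds reproduce
  templates, models, and analyses bit-for-bit.

## Known limitations

* The λ₁/λ₂ penalties of the deformable objective map onto demons smoothing
  kernels only heuristically; different σ choices change how much outline
  detail is preserved.
* RFT assumes a stationary, reasonably smooth field; at FWHM near the
  lattice floor the threshold is conservative.
* The template carries cohort-mean intensities but cannot represent
  anatomy absent from the cohort (e.g. a pes planus midfoot footprint
  larger than the template silhouette is partly excluded from testing).
* Single-case results inherit registration error; the Dice floor and the
  QC overlay are the guard rails, not a guarantee.
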