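# Methods

## Problem and model overview

The package studies how the injected activity `A_inj` and patient habitus
jointly determine liver signal-to-noise ratio (SNR_L) and tumour
contrast-to-noise ratio (CNR) in [⁶⁸Ga]Ga-DOTA-TOC PET, and derives a
prescription rule that holds SNR_L constant across body sizes.  Noise in
the reconstructed image is driven by detected counts, which fall with
habitus through two mechanisms: 511 keV attenuation along longer tissue
paths, and dilution of a fixed injected activity over a larger body
(`A_vox ∝ 1/w_T` at fixed SUV).  Everything else in a clinical chain —
time-of-flight, detector geometry, deadtime — modulates the absolute
noise level but not this structure, and is deliberately excluded; a
single calibrated sensitivity scalar anchors the simulation to a clinical
operating point instead.

## Phantom cohort

Phantoms are integer code images (air, soft tissue, lungs, liver, spleen,
kidneys, pancreas, stomach wall, bladder contents, tumours).  The body is
a tapered elliptical column without arms, covering mid-thigh to forehead
(axial length 0.75 × height, in-plane aspect ratio 0.62); a fixed
piecewise-linear axial profile narrows the column at hips, shoulders,
neck and head.  Organs are ellipsoids at fixed fractional positions, with
a small seeded jitter (±1% of the semi-axes) between phantoms.  Organ
masks are realised as the `n = round(V/V_vox)` voxels closest to the
organ centre in the normalised ellipsoidal metric, so every requested
volume is hit to within half a voxel on any grid.

The default cohort mirrors the published eight-phantom habitus series
(heights 1.53–1.82 m, weights 56–120 kg, nominal BMI 19–38 kg/m²).  Two
printed rows are internally inconsistent (P2's height/weight imply BMI 22
and BSA 1.82, printed 23/1.81; P8's BMI 37.45 is printed as 38); the
printed integers are kept as *nominal* labels while all computed metrics
derive from height and weight.

Weight is the voxel sum of density and is forced exactly to the target by
rescaling the soft-tissue density (kept in 0.8–1.2 g/cm³; in practice the
rescale is < 1%).  Torso semi-axes are derived from weight and height at
unit soft-tissue density, so heavier phantoms are wider and attenuate
more — the printed abdominal circumferences are *not* imposed, because
they are volumetrically incompatible with the printed weights under any
arms-free column model (e.g. 56 kg cannot fit behind a 72 cm maximal
perimeter at physiological density).  Measured circumference (marching
squares on a lightly smoothed mask, maximum over slices) is used as the
candidate body-size parameter instead.  Organ volumes scale linearly with
weight from a 70 kg reference (liver 1500 mL, lungs 3500 mL, spleen
180 mL, kidneys 300 mL, pancreas 100 mL, stomach wall 150 mL, bladder
180 mL), which keeps each organ's share of the injected activity
habitus-independent.

Body metrics: BMI = w/h²; BSA by Du Bois (0.007184·W^0.425·H_cm^0.725);
circumference as above.  Standard deviations throughout the package are
population SDs (divisor N).

## Activity model

`A_vox = A_inj · SUV_vox · V_vox / w_T` with w_T in grams and V_vox in mL
(SUV = 1 is the whole-body-average concentration).  High-uptake SUVs:
bladder 12.0, kidneys 9.7, liver 9.5, pancreas 5.5, spleen 23.2, stomach
wall 7.0, tumours 22.9.  The rest-of-body values are calibration
constants: lungs 0.35 and soft tissue 0.021, chosen once so the imaged
fraction of injected activity is ≈ 40% for every cohort phantom (the
clinically observed recovery; the low soft-tissue value absorbs, in one
constant, the out-of-field activity and excretion that the torso-only
phantom cannot represent).  ⁶⁸Ga decay uses T½ = 67.71 min; a 60 min
uptake window is the default, and no biological redistribution is
modelled.

## Acquisition and reconstruction

Each axial slice is acquired independently in 2-D parallel-beam geometry
(default 96 views over 180°, radial bins at the voxel pitch).  A sparse
system matrix splats each voxel onto its two nearest radial bins per
view; line integrals are the same matrix times the pixel pitch.  The
expected sinogram is

    λ = s · t · exp(−∫μ) ⊙ (A a) + r,

with μ = 0.0096 mm⁻¹ × density (water at 511 keV), `s` the scalar
sensitivity, `t` the time per bed position (default 3 min), and `r` a
uniform background carrying a fraction b = 0.3 of total counts (scatter
and randoms collapsed into one known term).  Counts are Poisson.
Deadtime and pile-up are omitted, as in the Monte Carlo chain this
stands in for.

OSEM (default 3 iterations × 16 interleaved subsets) uses the same
attenuated system model including the background term, so the
reconstruction is corrected for attenuation and background by
construction; voxel estimates are converted to Bq/mL and post-filtered
with a 5.5 mm transaxial / 4 mm axial FWHM Gaussian.  All slices are
updated simultaneously (shared system matrix), which is what makes the
full cohort × protocol × seed ensemble run in minutes.

The sensitivity `s` is calibrated once per experiment by a
square-root-law-accelerated bisection so that the cohort median SNR_L
under the weight-linear protocol equals 14.0 (±0.2), using a noise
realisation fixed by a child seed; `s` is then frozen for every protocol,
phantom, and ensemble member.

## Metrics

* NEMA-style: six spheres (37–10 mm) at 4:1 contrast in a synthetic
  elliptical fixture; 12 template background-ROI positions (a fixed
  fractional layout shipped as package data, ≥15 mm from edge and
  spheres) on 5 slices (0, ±1 cm, ±2 cm) → 60 ROIs per diameter.
  SNR_i = x̄_B/σ_B with σ_B pooled over all ROI voxels — note this is the
  source analysis's literal definition, not NEMA NU-2 "background
  variability".
* Liver: spherical VOI at the deepest point of the liver (distance
  transform, deterministic tie-break), excluding tumours;
  SNR_L = mean/SD, CNR = (x̄_T − x̄_L)/σ_L over the true tumour mask.
  Rose criterion inclusive at CNR ≥ 5.

## Desk-scale settings and their rationale

The pipeline default grid is 112×112 in-plane at 5.46×5.46×5.58 mm (the
reference 256×256 / 2.73 mm grid is the phantom-builder default and all
operations accept either).  One bed position covering the liver (±30 mm)
is simulated.  At this voxel size a 25 mm VOI holds only ~50 voxels, and
the SD estimator noise alone (~10–15%) would dominate the 8-phantom SNR
range that the protocol comparison measures; the pipeline therefore uses
a 40 mm VOI (~200 voxels), which matches the voxel count of a 25 mm VOI
at the reference resolution.  The metric function itself defaults to
25 mm.  Tumour seeding excludes the VOI sphere plus a 5 mm margin, so
the "uniform part of the liver" the VOI needs always exists; seeds are
otherwise uniform over the liver interior (10 mm boundary margin,
28 mm pairwise separation) and are reused across phantoms through their
fractional position in the liver bounding box.

## What the synthetic data does and does not show

The generator reproduces: Poisson noise scaling (ROI SNR ∝ √(A·t)),
monotone SNR loss with attenuating body size, organ/tumour uptake ratios,
partial-volume suppression of small-sphere contrast, and the ~40% imaged
activity fraction.  It does not reproduce: anatomical realism, organ
motion, intra-patient uptake variability, TOF noise structure, 3-D
resolution properties, or absolute count rates — so absolute SNR values
are meaningful only relative to the declared calibration anchor, and
conclusions transfer to real scanners as trends, not numbers.

## Numerical choices

* Nearest-n mask realisation with lexicographic (z, y, x) tie-break makes
  phantom and tumour construction bit-deterministic.
* Power-law fits run on the linear scale (nonlinear least squares seeded
  by the log-log regression); the log-log fit is exposed as a diagnostic.
  R² = 1 − SS_res/SS_tot about the mean of SNR_Norm; a zero-variance
  response returns d = 0 with R² = 0.  Ties in the parameter selection
  prefer weight.
* Units in the normalisation/prescription chain are MBq and minutes —
  the only convention consistent with the published prescription table.
* OSEM guards zero-sensitivity voxels and empty rays explicitly; images
  are non-negative by construction.
* The Rose threshold is inclusive with a 1e−9 tolerance so exact
  boundary cases classify deterministically.
* Randomness: one master seed; every stochastic stage (seeding,
  calibration, each phantom × protocol acquisition) draws from a
  dedicated `SeedSequence` child, so experiments are bit-reproducible
  and ensemble members are independent.

## Known limitations

Single bed position (no multi-bed stitching or axial overlap); 2-D slice
independence understates 3-D noise correlations; the uniform background
is cruder than measured scatter/randoms profiles; the torso model cannot
match printed circumferences (see above); cohort BMI labels follow the
published rows even where internally inconsistent.
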