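# Methods

## The dose model

`mammodose` computes the **average absorbed breast dose** (2ABD): the
average of the absorbed dose over the depth of a uniformly compressed
breast.  With incident air kerma `k_ai` at the upper breast surface and
an effective exponential energy-absorption coefficient `mu_en` (cm⁻¹)
for water-equivalent soft tissue (density ≈ 1.0 g/cm³), the dose at
depth `x` is `k_ai · exp(-mu_en·x)` and its depth average over a breast
of thickness `d` has the closed form

    2ABD = k_ai · (1 − e^(−mu_en·d)) / (mu_en·d)

The factor `(1 − e^(−u))/u` is implemented with a guarded small-argument
branch (3-term series below `u = 1e-6`, truncation error < 1e-19) to
avoid cancellation; `math.expm1` is used on the main branch.  It is
strictly decreasing in `u` and lies in (0, 1], so 2ABD ≤ k_ai always,
with equality exactly at `d = 0`.

The incident air kerma is reconstructed from acquisition parameters
rather than measured per exposure.  In the mammographic range
(22–34 kVp) the tube output per mAs at the image plane is linear in
tube voltage, so

    k_ai = (Y_tb / Y_0) · (α·kVp + β) · mAs · (FID / (FID − d))²

where `α` (mGy mAs⁻¹ kVp⁻¹) and `β` (mGy mAs⁻¹) are fitted on a
reference tube of yield `Y_0`, `Y_tb` is the yield of the clinical tube
(both defined at the same reference voltage, 28 kVp by default), `FID`
is the fixed focus-to-image distance and the inverse-square factor
moves the reference point from the image plane to the breast entrance
surface at `FID − d`.  All quantities are handled in cm, mGy, kVp, mAs
and cm⁻¹ (HVL in mm Al); DICOM thicknesses in mm are converted at
ingest.

`Y_0` in the yield ratio is the *measured* reference yield, not the
line value `α·28 + β`.  The two are conceptually close but numerically
distinct — across the five bundled combinations they differ by 0.7% to
6.9% — and using the measured value is what reproduces the bundled
cross-device kerma survey within 2%.  The package still exposes the
line-vs-yield comparison as a self-consistency diagnostic; note that a
2% agreement between them should *not* be assumed.

A kVp outside the calibrated interval [22, 34] produces a warning and
proceeds: the linearity claim only covers that interval, and
extrapolation is an informed user choice rather than an error.

## Calibration estimators

**Kerma line.**  `kerma/mAs` is regressed on kVp by ordinary least
squares (`scipy.stats.linregress`), giving `α`, `β`, their standard
errors, R² and the slope–intercept covariance `−x̄·se(α)²`.  Replicate
measurements at identical (kVp, mAs) are averaged before fitting,
mirroring the five-repeat measurement protocol; a pooled mode is
available.  Fits are unweighted — the protocol supplies no per-point
sigmas.

**Attenuation.**  Beam intensity under 0–5.5 cm of solid water is
fitted to `I(x) = I0·e^(−mu_en·x)`.  The default is nonlinear least
squares in intensity space (`scipy.optimize.curve_fit`), initialised
from the log-linear closed form; a `loglinear` mode returns the
log-space OLS directly.  R² is always computed in intensity space.
The two estimators weight the errors differently and therefore disagree
at first order in the noise: empirically the relative `mu_en`
disagreement is ≈ 0.7× the relative noise sigma in the mean (≈ 2% worst
case at 1% noise), shrinking proportionally as the noise decreases.
The nonlinear estimator is the default because it is unbiased under
additive intensity noise.

**Per-combination average `mu_en`.**  `mu_en` varies only weakly with
kVp over the calibrated range, so a single per-combination average (the
unweighted mean of the per-kVp fits) is the default coefficient; linear
per-kVp interpolation (clamped at the table ends) is an opt-in mode.
The sigma attached to the average is `max(mean of per-kVp sigmas,
SD/√n)` — the per-fit error floor, or the standard error of the mean
when the spread dominates.  This rule reproduces every bundled
per-combination sigma; the alternative of quoting the raw sample SD
would more than double the Mo-Mo value and was rejected.

**Tube yield.**  `Y = mean(kerma/mAs)` over replicates at the reference
kVp, with the sample SD as 1σ (0 with a warning for a single
measurement).

## Bundled constants

The package ships measured constants for five anode-filter
combinations:

| combination | α (mGy/mAs/kVp) | β (mGy/mAs) | Y₀ (mGy/mAs) | mu_en (cm⁻¹) |
|---|---|---|---|---|
| Mo-Mo | 0.00997 ± 0.00005 | −0.186 ± 0.001 | 0.0938 ± 0.0008 | 0.91 ± 0.04 |
| Mo-Rh | 0.00892 ± 0.00008 | −0.180 ± 0.002 | 0.0739 ± 0.0008 | 0.73 ± 0.02 |
| Rh-Rh | 0.0078 ± 0.0002 | −0.149 ± 0.006 | 0.0707 ± 0.0003 | 0.68 ± 0.04 |
| W-Rh  | 0.00271 ± 0.00004 | −0.047 ± 0.001 | 0.031 ± 0.001 | 0.57 ± 0.02 |
| W-Ag  | 0.00371 ± 0.00009 | −0.066 ± 0.003 | 0.0391 ± 0.0009 | 0.53 ± 0.02 |

plus the per-kVp `mu_en` tables behind the averages.  The Mo/Rh
combinations were characterised on a GE Senographe DS (FID 63.5 cm) and
the W combinations on a Hologic Selenia Dimensions.  The Selenia's FID
is not part of the characterisation data; the bundled registry uses the
vendor-nominal 70 cm source-image distance for that device, so W-anode
dose values on the bundled registry carry that nominal-geometry caveat.

## Uncertainty propagation

2ABD uncertainty uses the first-order delta method with analytic
partial derivatives with respect to the eight inputs α, β, Y₀, Y_tb,
kVp, d, FID and mu_en, summed in quadrature, with an optional α–β
covariance cross term (off by default; the bundled constants carry only
marginal fit errors).  The product structure makes the log-derivatives
simple; the attenuation-factor term uses `d log f/du = 1/expm1(u) − 1/u`
with its own small-argument series.  A finite-difference oracle
(central differences, 1e-5 relative step) rebuilds the sigma and agrees
with the analytic result to better than 1e-4 across random input grids.

The bundled default budget takes the fit sigmas from the calibration,
the yield sigma from the device registry, σ_d = 0.5 cm (the thickness
tolerance quoted by device technical manuals) and treats kVp, mAs and
FID as exact set values.  Under that budget the relative 2ABD
uncertainty over the bundled clinical cohort is 10–15%, dominated by
the thickness term at small `d` and by the Rh-Rh line-fit errors at
large `d`.  Published audits of the same cohort quote 17–33%; reaching
that band requires additional per-input sigmas (e.g. a non-zero kVp
uncertainty of 1–2 kVp) that are not part of the published record, so
the package does not silently assume them.  The band comparison is kept
as a (currently failing) plausibility check rather than being tuned.

Reference AGD values (below) carry a flat 20% relative sigma, the
accepted overall error of conversion-factor dosimetry; only 1σ values
are reported throughout (no coverage factors).

## Reference AGD and comparison

For comparison, the package evaluates the two conversion-factor
formalisms: Dance (`AGD = k_ai·g·c·s`, with `g` the 50%-glandularity
kerma-to-AGD factor, `c` the composition correction — age-stratified
into 40–49 and 50–64 groups, values within [0.885, 1.306] — and `s` a
flat per-spectrum factor) and Wu (`AGD = k_ai·D_gN`).  The published
factor grids are third-party tables and are **not** redistributed: the
package defines the CSV grid format (thickness grid across, HVL grid
down, sidecar JSON for name/stratum/combination) and interpolates
bilinearly on (HVL, thickness) via `scipy`'s `RegularGridInterpolator`.
Interpolation is exact at nodes; out-of-grid queries raise, or clamp to
the boundary with a warning when explicitly enabled.  Ages outside both
c-strata map to the nearest group with a warning; an explicit
glandularity with a glandularity-binned table overrides age.  The
`compare` command flags per-exam agreement as overlap within combined
uncertainties: `|2ABD − AGD| ≤ σ(2ABD) + σ(AGD)`.

## Synthetic data

The generators emulate the measurement designs the estimators were
built for: kerma over a 22–34 kVp grid at mAs 10–100 with five
replicates, transmission over twelve depths 0–5.5 cm, and exam cohorts
with kVp 25–30, mAs 18–114, thickness 2–7 cm, screening ages 40–64 and
combination-typical HVLs.  Default noise is multiplicative Gaussian
with σ = 1%, the repeatability scale suggested by the ~1% relative SDs
of the bundled reference yields; intensities are redrawn if a draw goes
non-positive.  Every generator is a pure function of its seed.
Header-only DICOM fixtures carry exactly the attributes the reader
consumes.

What the synthetic data does *not* emulate: spectrum shape (only the
linear-in-kVp and exponential-in-depth laws), scatter, heel effect,
paddle transmission (absorbed implicitly by the calibration
measurements), detector energy response, and any correlation between
patient parameters.  Passing tests therefore demonstrate the
correctness of the estimators and the dose algebra under the model's
own assumptions, not the adequacy of those assumptions for any
particular clinical unit — that is what the bundled cross-device kerma
survey reproduction (within 2%) and the patient-dose reproduction
(within the 0.1 mGy print precision) speak to.

## Numerical and design choices

* Attenuation-factor series switch at `mu_en·d = 1e-6`; branch
  continuity verified to 1e-10.
* The quadrature oracle for the factor uses Simpson's rule on 10⁴
  panels (error ~1e-14); composite trapezoid at the same resolution has
  relative error `h²μ²/12 ≈ 8e-8` at μ = 1.2, d = 8 and cannot support
  a 1e-8 tolerance.
* `d = 0` is exact (2ABD = k_ai), not a limit evaluation; `d ≥ FID` is
  a hard geometry error.
* Kerma components (yield ratio, line × mAs, inverse square) are stored
  with the result and must reconstruct it to 1e-12 relative.
* Per-exam failures in batch commands never abort the batch: exit code
  0 all-ok / 2 partial / 1 fatal, with errors recorded per row.
* Report CSVs round doses to 0.1 mGy (the convention of clinical dose
  tables) at serialisation only; the JSON report keeps full precision.
* Monte-Carlo study sizes (100 seeds for attenuation recovery, 200 for
  the kerma line, 50–100 for agreement and propagation grids) were
  chosen so that Monte-Carlo error is well below the asserted
  tolerances while the whole suite stays interactive.

## Known limitations

* No breast-density/glandularity correction enters 2ABD by design; the
  index trades that refinement for direct computability from recorded
  acquisition parameters.
* No scatter/heel/paddle modelling beyond what the calibration absorbs.
* HVL is an input (needed only for the reference AGD comparison), never
  computed from the attenuation series.
* The uncertainty budget behind the published 17–33% relative-error
  band is underdetermined; see the propagation section.
* DICOM support is header-only Part-10 reading (no PACS networking, no
  pixel data).
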