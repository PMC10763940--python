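# Methods

## The measurement model

A 96-well plate holds TMB–H₂O₂ reaction mixtures; Cr(VI) oxidizes TMB to a
blue product, and the blue color absorbs red light, so the mean red
intensity of a well imaged on a fixed scanner fixture falls linearly with
Cr(VI) concentration over a validated range. `platesense` models a well's
response as

    R = m·X + c + ε,    ε ~ N(0, σ_w²)

with X the concentration in ppb, R on the 8-bit 0–255 scale, and ε the
well-to-well noise (replicate chemistry plus illumination variation).
Everything downstream — calibration, inversion, detection limits — is
ordinary linear-regression machinery applied to this line. The bundled plate
calibration (`platesense.datasets.PLATE_CALIBRATION`) has m = −0.06134 ±
0.00222, c = 100.49757 ± 0.63949, and a validated range of 25–600 ppb; the
companion spectrophotometer line (absorbance at 650 nm vs ppb) is bundled as
`SPECTRO_CALIBRATION`.

## Well location and feature extraction

Wells are located from the layout's template grid, not by blob detection:
the scanner fixture holds the plate rigidly, so a deterministic grid is both
faithful and fully testable. An optional brightness-centroid refinement
(±3 px) exists for slightly misregistered scans and is off by default. Each
well is reduced to the arithmetic mean of each channel over a central disk
of radius `roi_fraction` (default 0.6) times the well radius; the central
disk avoids meniscus and edge shading, and a median statistic is available
for robustness to specks. The composite channel is defined as exactly
mean R + mean G + mean B. Pixel coordinates use the image convention: origin
top-left, x rightward, y downward.

The ROI radius and averaging statistic behind the published well index are
not documented anywhere we could find; mean-R over a 0.6-radius central disk
is this package's choice, and both knobs are configurable.

## Calibration and uncertainty

`CalibrationCurve` fits by OLS using the centered closed forms
(slope = Sxy/Sxx, SE(slope) = s/√Sxx, SE(intercept) =
s·√(1/n + x̄²/Sxx), s² = RSS/(n−2)) and reports R² and adjusted R². Fits
require ≥3 points and ≥2 distinct concentrations; a flat (zero-slope)
response is a legitimate intermediate fit during screening and yields
undefined (NaN) detection limits rather than an error. When replicate wells
are available the fit pools all (conc, response) points rather than
per-concentration means, so the standard errors retain their per-observation
meaning.

Detection limits are LOD = 3.3·σ/|m| and LOQ = 10·σ/|m| (their ratio is
10/3.3 by construction). σ is selectable:

* `slope_se` (default) — the convention under which the bundled
  calibration's published pair (0.12, 0.36 ppb) is internally consistent
  with its printed ±0.00222 slope SE;
* `intercept_se` — the ICH-style blank-dispersion convention;
* `residual_sd` — the pooled residual SD.

The three can differ by orders of magnitude; persisted models record which
was used. Limits are stored at full precision and reported to 2 decimals.

## Selection procedures

**Channel.** Each candidate (R, G, B, R+G+B) is regressed on concentration;
the highest adjusted R² wins, with exact ties broken by the fixed order R,
R+G+B, G, B. Requires ≥3 concentration levels.

**Reading time.** Per time point, response is regressed on concentration.
Times whose |slope| is below 25 % (`slope_floor_frac`) of the largest
per-time |slope| are discarded as undeveloped (the early flat phase); among
the remainder the earliest time attaining the maximal adjusted R² is
returned. If every time is flat the error message advises longer incubation.

**Reagent dose.** The dose-response curve is monotone-smoothed (isotonic
regression), then the plateau is the maximal suffix of doses within
`plateau_tol` (default 5 %, relative) of the maximum smoothed response; the
smallest dose on the plateau is the optimum. If only the top dose qualifies,
the curve is still rising there and the result is flagged `not_saturated`
(top dose returned with a warning status). The 5 % tolerance is this
package's default; no published value exists.

## Quantification and the N.D. rule

Inversion is X = (r − c)/m, held at full precision (reports round to
3 decimals). A prediction is N.D. (non-detectable) exactly when X falls
outside the validated linear range; the interval is **closed** at both ends
so that the calibration endpoints themselves are reportable — one ulp beyond
either endpoint is N.D. Replicate wells are averaged on the response scale
before inversion, matching linear-calibration practice. The N.D. rule is
applied per instrument: a sample can be in range for the spectrophotometer
and N.D. for the plate imager.

## Validation metrics

Recovery % = 100·measured/spiked and RE % = 100 − recovery %, an exact
identity. (The bundled spike experiment's published 250-ppb RE of −0.3024
contradicts its own recovery of 100.0324 %, which implies −0.0324; the
identity is treated as authoritative and the inconsistent printed value is
not reproduced.) The paired-method error is |test − reference|/reference,
kept as a *fraction* (0.068 ≈ 6.8 %) to stay faithful to the bundled survey
table's values; pairs with error above `outlier_tol` (default 0.5, which
flags survey samples 1 and 24) are flagged, not removed. Pearson r is the
product-moment correlation over non-N.D. pairs: on the bundled survey it is
0.916 over all 22 pairs and above 0.98 with the two flagged outliers
excluded — which subset produced the originally reported 0.99 is not
documented, so both are computed and neither is asserted. Ion selectivity is
the blank-subtracted signal ratio of each species to Cr(VI), flagged above
`interference_tol` (default 0.1).

## The synthetic generator

`GeneratorConfig` defines the simulated study conditions; all generators are
deterministic under the mandatory seed.

* **Truth lines.** Red: slope −0.06134, intercept 100.49757 (the bundled
  calibration). Green and blue: near-zero slopes (−0.0014, −0.0008) with the
  same noise, so they show weak-to-negligible linearity and channel
  selection is exercised realistically rather than trivially.
* **Noise.** Per-well Gaussian sd 0.5 (R units) and per-pixel Gaussian sd
  2.0, chosen so a pooled ~500-well calibration lands near adjusted
  R² ≈ 0.99.
* **Concentrations.** The ten standard levels 1, 25, 50, 75, 100, 200, 400,
  600, 800, 1000 ppb, 9 replicate wells each on a default plate (pooled
  tables can use any replicate count).
* **Rendering.** Wells are disks on a dark background; channel means are
  quantized to 8 bits. The truth table records both the analog model mean
  (`target_mean_*`) and the quantized rendered mean (`rendered_mean_*`);
  they differ by at most half an intensity step, which corresponds to
  ~8 ppb through the red-channel slope and is the irreducible error floor of
  a noise-free round trip. A mean outside [0, 255] (e.g. 5000 ppb through
  the red slope) is rejected with the offending concentration named.
* **Kinetics.** Development follows f(t) = 0 until an onset time (default
  2/3·t*) and 1 − exp(−3(t−onset)/(t*−onset)) after, so f(t*) ≈ 0.95: flat
  early phase, then saturating development, mirroring an assay whose color
  change is negligible before development begins. Default t* = 15 min.
* **Dose-response.** Michaelis-type saturation r(d) = Rmax·d/(k + d). The
  chromogen preset (k = 0.11 mM on a 0.1–1.5 mM grid) places the
  5 %-of-plateau crossing between the 0.8 and 0.9 mM samples, and the
  oxidant preset (k = 2.8 mM on a 10–300 mM grid) between 40 and 50 mM;
  amplitudes keep responses inside the absorbance bands observed for those
  titrations (0.0047–0.0685 and 0.0243–0.1523 AU, taken as containment
  envelopes — a strict Michaelis curve cannot pass through both printed
  endpoints and still plateau mid-grid). Noise is opt-in (default 0) because
  the plateau margins near the tolerance threshold are ~4×10⁻⁴ AU.

What the generator does **not** emulate: vignetting, specular highlights,
bubbles, dust, plate misregistration beyond a few pixels, spatial
illumination gradients, or non-Gaussian noise. Passing tests therefore
demonstrate the correctness of the analysis chain under the stated model,
not robustness to real-scanner artifacts.

## Numerical choices

* OLS by centered normal equations; tests cross-check against both an
  independent brute-force oracle (to 1e−10) and `scipy.stats.linregress`.
* Flat data (zero total variance) is assigned R² = 0, so uninformative
  channels never win selection.
* Concentrations report to 3 decimals, LOD/LOQ to 2; all stored values are
  full precision. Reports render N.D. as the literal `"N.D."`.
* Adjusted R² uses n − 2 degrees of freedom (straight-line fit).

## Problem sizes in tests and the acceptance script

The statistical acceptance checks use 1,000 random OLS instances, 2,000
seeded 500-well calibration recoveries, 100 channel-selection and 50
reading-time runs at well level, and three fully rendered plates (96 wells,
~394×274 px) for the pixel-to-ppb round trip; the whole suite runs in a few
seconds. The acceptance script's targets are deterministic inversions of
the bundled calibration.

## Known limitations and data caveats

* Bundled survey sample 3: its reported concentration (283.752 ppb) was
  evidently computed from an unrounded well index — re-inverting the rounded
  printed index (83.092) gives 283.756 ppb, 0.004 ppb away. The
  corresponding acceptance case asserts the reported value at ±0.001 ppb
  and therefore fails by arithmetic necessity; it is kept as an honest
  record of the discrepancy.
* No inverse-regression confidence intervals on predictions; no weighted or
  nonlinear (4PL) calibration; no Bland–Altman/Deming method comparison.
* The spectrophotometer line's constants do not reproduce the survey's
  spectrophotometer column (implied intercept differs); no check is built
  on that column.
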