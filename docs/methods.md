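# Methods

## The error model and its estimation

Frame-level chest-wall errors are modelled as `y[p,f,k] = M + a[p] +
b[p,f] + e[p,f,k]` with independent zero-mean Gaussian effects for patient
(`Σ²pt`), fraction nested in patient (`σ²fr`) and frame residual
(`σ²intra`). The model treats frames within a breath-hold as exchangeable:
no temporal autocorrelation, no heteroscedasticity across patients, and no
field-level variance component — the two tangential fields of a fraction
share the fraction effect and differ only through residuals. Crossed
effects and 3-D/rotational motion are out of scope; the resulting margin
is one-dimensional, along the measurement direction in the beam's-eye-view
plane.

Estimation is restricted maximum likelihood. Because each fraction cell
enters the covariance matrix as compound symmetry nested inside a
patient-level rank-one term, the restricted likelihood collapses onto
per-cell sufficient statistics (count, mean, within-cell sum of squares)
via Sherman–Morrison; the derivation and the exact expressions are in the
`varcomp` module docstring. A cohort of ~3·10⁵ frames reduces to ~400
cells, so a fit costs milliseconds and profile intervals stay cheap.

Numerical choices:

* The optimiser works on log-variances (L-BFGS-B, bounds
  `[1e-10·Var(y), 1e6·Var(y)]`), started from expected-mean-squares moment
  estimates floored at `1e-3·Var(y)`. A solution at the lower bound is a
  zero-boundary estimate: the component is reported as exactly 0 and
  flagged. Line-search failures on very flat surfaces are polished by
  Nelder–Mead; a fit is accepted when the optimiser reports success or the
  projected gradient is below 1e-3.
* All-constant input data (restricted likelihood unbounded as
  `σ²intra → 0`) short-circuits to the exact degenerate answer: mean = the
  constant, all SDs 0.
* Identifiability is checked before fitting: ≥2 patients, ≥2 fractions for
  at least one patient, ≥2 frames in at least one fraction; violations
  raise an explicit error rather than returning a boundary fit.

Confidence intervals: profile restricted likelihood for the three SDs
(deviance cut at `χ²₁(level)`, endpoints found by bracketed root-finding
on the variance scale, mapped to SDs by the square root; a boundary
component yields a one-sided interval flagged as such), and a Wald
interval from the GLS variance for the overall mean. A parametric
bootstrap (resampling the sufficient statistics from the fitted model) is
available as an alternative for all parameters. `level=0` degenerates
every interval to its point estimate. On balanced designs with interior
solutions the REML estimates coincide with the closed-form
expected-mean-squares ANOVA solution; the test suite verifies this against
an independently coded EMS solver, and the fit was cross-checked once
against lme4 during development.

## Margin recipe

`effective_errors` implements `Σ²eff = Σ²pt + σ²fr/N` and
`σ²eff = (1−1/N)σ²fr + σ²intra`; `ptv_margin` applies
`2.5 Σeff + 0.7 σeff`. The 2.5/0.7 coefficients (95% minimum CTV dose for
90% of patients) are defaults, not constants, so other margin recipes can
be explored. Margins are reported at full precision and rounded only for
display — rounding the effective errors first can move the printed margin
by ~0.01 mm.

## What the synthetic generator emulates

`simulate_errors` is the sampling counterpart of the model above, at the
study conditions by default: 25 patients × 16 fractions × 2 fields,
breath-holds `N(20.4 s, 1.7 s)` (one hold per field), nested SDs
(0.82, 1.19, 1.63) mm, mean 0.30 mm. The cine frame rate is not a
published quantity; the default of 19 Hz was calibrated once so that the
cohort-scale frame count (~3.10·10⁵) matches the study's analysed total,
and per-field counts are `round(hold_s × rate)`. Gaussian draws are not
truncated: real beam-hold gating would clip large excursions, but no
clipping rule is published, so none is modelled.

`simulate_rpm_trace` produces a breath-hold plateau with a two-tone
sinusoidal ripple plus slow drift, rescaled so the amplitude statistic
(max − min of the abdominal wall position) hits the requested value
exactly; only that statistic is meaningful, the waveform shape is a
documented invention. Gate thresholds bracket the plateau with a
`max(0.25 mm, 25%)` guard band.

`render_frames` draws an oriented soft-tissue/lung step as an erf profile
of width `blur_sigma_px` (default 1.5 px) plus additive Gaussian noise
(default 40 counts on a 1200-count step over a 400-count base), at a
sub-pixel edge position set by the isocenter-plane offset divided by the
isocenter pixel size `pitch × 100/SID`. Default geometry: 192×256 frames
spanning a 43 cm square detector at SID 160 cm (pitch 1.68 mm, isocenter
pixel 1.05 mm). The frame count is kept small because every stability
criterion is expressed in pixels and is scale-free; full 1280×1280 frames
render identically, just slower. What the renders do *not* emulate:
anatomy (ribs, lung texture), scatter and beam-profile gradients, detector
lag/ghosting, field-edge penumbra. Passing the round-trip and stability
tests therefore shows the detector chain is correct and sub-pixel stable
on step-edge images, not that it is robust to every clinical artefact —
the multi-edge tie-break below is the only concession to anatomy.

## Edge detection

Within the ROI (set at isocenter level), scikit-image's Canny
(smoothing σ = 2 px, absolute hysteresis thresholds 20/60
gradient-magnitude counts) acts as the edge-presence gate: if nothing
survives hysteresis the frame is flagged `no-edge` and excluded from error
statistics (counted in the per-stack quality report; >50% no-edge flags a
warning — exclusion-with-reporting is this package's choice, as is the
whole handling of undetectable frames). The measured coordinate comes from
the mean absolute-gradient profile along the direction perpendicular to
the field's long axis (the profile is taken by collapsing the ROI along
the long axis rather than rotating the image, avoiding interpolation);
among candidate peaks ≥50% of the maximum, the largest wins, near-ties
(≥95%) are broken toward the previous frame's position, else toward the
reference, and the frame is flagged `multi-edge-resolved`. Sub-pixel
refinement is a parabolic fit through the three profile samples around the
peak — any scheme meeting the sub-pixel stability bound would do; the
parabola keeps the detector dependency-free and deterministic. Pixel
indices are 0-based with positions at pixel centres; the mm origin sits at
the frame centre along the measurement axis, deep inspiration signed
positive, and the reference (DRR) position defines zero error.

The printed-geometry ambiguity is worth noting: a 43 cm/1280 px detector
at SID 160 implies a 0.21 mm isocenter pixel, which cannot be reconciled
with a "0.47 mm²" isocenter pixel area; the package trusts the
divergent-beam formula and keeps all geometry configurable rather than
hard-coding either figure.

## Problem sizes and tolerances in the shipped checks

Stochastic checks compare estimates to generating truth within 3
Monte-Carlo standard errors computed from the design (normal-theory
mean-square variances, delta method to the SD scale) rather than
hard-coded bands. The recovery runs use 25×16 with 200 frames per fraction
(100 per field, 80,000 observations) — the full per-field frame count adds
residual degrees of freedom the patient- and fraction-level SEs barely
use, so this design measures the same thing at a fraction of the cost.
The interval-calibration study runs 200 replicates of an 8×6×30 design and
requires 95%±5% coverage for the inter-patient SD. The static-phantom
check renders 100 frames at the default geometry and requires per-frame
scatter < 1 detector pixel.

## Known limitations

* Within-breath-hold autocorrelation of frames would inflate the apparent
  precision of `σintra` (and its interval) relative to truly exchangeable
  residuals; it is noted, not modelled.
* The profile/Wald interval mix is a convention choice; interval methods
  for variance components differ in small samples, which is why the
  bootstrap alternative is exposed.
* The margin model is one-dimensional and dosimetry-free: no coverage
  probability is recomputed by dose calculation, and no rotational or 3-D
  setup error enters.
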