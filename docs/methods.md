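# Methods

This note documents the models, numerical choices and known limits of
`pupilbench`.  It states no empirical result the test suite or
`scripts/acceptance.py` does not itself compute.

## Pupil-diameter models

The eight closed forms are evaluated exactly as published, at full
floating precision, with every constant carried at its printed value —
no coefficient is re-fit.  The Watson & Yellott unified model composes
the Stanley & Davies curve on the monocularly attenuated corneal flux
`L·α·e/846` (`e = 0.1` monocular, `1` binocular) with a linear age
correction about the reference age 28.58 years.  The age coefficient
`0.02132 − 0.009562·D_SDW` changes sign at `D_SDW ≈ 2.23 mm`: large
pupils shrink with age (senile miosis) while pupils already at the
bright-light floor grow slightly.  Evaluation outside the 17–83 y
range of the age-correction data warns; Blackie & Howland warns above
its stated 10 cd/m² validity ceiling.

### Adapting-field conversions

Field sizes enter the flux models as areas in deg².  Four conversions
are provided:

* `product` (`αx·αy`, rectangular) and `circle_area` (`π/4·D²`) — the
  flat-field rules;
* `spherical_cap` — the exact solid angle `6566π(1 − cos(D·π/360))`,
  applied to the circular-equivalent diameter
  (`D = 2√(αx·αy/π)` for rectangles);
* `legacy_toolbox` — `(D/2)·π`, a dimensionally wrong approximation
  found in circulated pupil toolboxes, kept only to reproduce its
  output and always warning.

The flat rules overestimate the solid angle of wide fields (≈2% at
53°), so a flat conversion above 15° raises unless explicitly
overridden.  The shipped benchmark default *is* such an override: a
700 mm square field at 700 mm distance is represented as a circular
field of `2·atan(0.5) = 53.13°` converted with `circle_area`, because
that convention reproduces the reference worked examples (the
spherical-cap area would shift the unified-model prediction by
≈+0.007 mm).  Whether the reference evaluation used 53.1° or the
unrounded 53.13° is not stated; the default is the unrounded value,
and the two differ by <0.001 mm in the prediction — below the 0.002 mm
comparison tolerance used throughout (the printed examples themselves
mix truncation and rounding in the third decimal).

## Colorimetry

All metrics are trapezoidal integrals on a common 1 nm grid from 380
to 780 nm; inputs on coarser grids (≤5 nm) are linearly resampled, and
radiance outside the grid is treated as zero.  Luminance is
`683·∫V(λ)Le(λ)dλ`; α-opic radiances use peak-normalized action
spectra so their unit is W·m⁻²·sr⁻¹.

### Action spectra are analytic stand-ins

The weighting functions are generated at import time from published
analytic forms rather than shipped as copies of the official
tabulations: the color-matching functions use the Wyman–Sloan–Shirley
multi-lobe Gaussian fits, rescaled to share one integral (which places
an equal-energy spectrum exactly at x = y = 1/3); the cone-opic and
melanopic curves combine the Govardovskii A1 pigment template (α and β
bands) with a single-exponential ocular-media density model for a
young eye, the pigment peak tuned so each filtered curve peaks at the
conventional α-opic peak (S 448, M 542, L 568, melanopic 490 nm).
These approximations track the standard curves to a few percent.
Every numerical test is therefore *self-consistent* — brute-force
fine-grid integration against the same tables — and passing tests show
correct integration machinery, not standards-compliant absolute
α-opic values.  Substitute the official tabulations where compliance
matters; only `action_spectra.py` would change.

### CCT

The correlated color temperature is found on a Planckian-locus lookup
table with 1% temperature steps (1000–25000 K, CIE 1960 `u,v` space,
i.e. `u′, 2v′/3`), refined by a parabola through the squared distance
over log-temperature.  `duv` is the signed locus distance (positive
above the locus); beyond |duv| > 0.05 the CCT is reported as undefined.
Round-trip error on Planckian radiators is far below the 0.5% the
package tests assert.  The algorithm is chosen for determinism and
testability; the reference analysis does not state one.

### Resampling accuracy

Metrics on 1 nm versus 5 nm input grids agree to 0.5% for spectra that
are smooth relative to both the 5 nm step *and* the local slope of the
weighting function.  Reading a steep action-spectrum tail against a
narrowband stimulus (e.g. S-cone-opic radiance of a 530 nm LED) can
deviate by ~1.5% at a 5 nm step; supply 1 nm spectra where tail values
matter.

## Trace preprocessing

Stages run in the order blink → quality → velocity → interpolate →
smooth; no stage alters the time axis or sample count.

* Blink-flagged samples are deleted with no temporal padding (the
  reference pipeline states none); padding is a natural extension but
  deliberately not default.
* Quality threshold 97% (ellipse-fit confidence), deletion not repair.
* The velocity filter differentiates consecutive present samples and
  removes the later sample of any pair whose velocity lies strictly
  outside the 0.007–99.993 percentile band, computed per recording.
  Percentile thresholds use attained order statistics
  (`method='lower'/'higher'`), so distributions without genuine
  outliers (constant traces, already-cleaned traces) lose nothing.
  Signed velocities are thresholded two-sidedly as printed, not
  |velocity|.  With fewer than 1000 present samples the percentiles
  are meaningless and the stage passes through with a warning.
* Gaps are filled linearly between bounding present samples; leading
  and trailing gaps take the nearest present value, because linear
  extrapolation can produce unphysical (even negative) diameters.
* Smoothing is Savitzky–Golay with window 3001 samples — the nearest
  odd window to a nominal 3000 samples, read as samples (25 s at
  120 Hz), not milliseconds — and polynomial order 3, a standard
  choice for physiological smoothing (the reference pipeline does not
  state its order).  Edges are handled by polynomial refit on the
  terminal window.  The first 3 s are returned unsmoothed so the
  phasic constriction onset is not flattened.
* Cleaning *consumes* the artifact annotations: the output trace has
  blink flags cleared and quality reset, since its diameters are
  repaired values.  Re-cleaning a cleaned trace is then exactly
  neutral in the 3 s lead and stable to ≈0.02 mm where the signal
  varies slowly; in the window that still overlaps the fast phasic
  onset (t ≈ 3–30 s) double-smoothing can move samples by up to
  ≈0.03 mm — intrinsic to re-applying a 25 s window to a 1.5 s
  transient, and bounded in the test suite at 0.05 mm.

Only the left eye of a recording is analyzed by default; eye selection
is metadata, not hard-coded.

## Benchmark statistics

Two deliberately separate data paths mirror the reference analysis:
*absolute* cleaned diameters feed the model-error computation (the
models predict absolute size, so no baseline is removed), while
*baseline-corrected* diameters feed the spectral-dependence ANOVA.

* Baseline = mean diameter over the final 10 s of the preceding
  anchor presentation (the convention of the age-dependency dataset
  behind the unified model's correction); window configurable.
* Extraction = 1 s mean centered on the requested exposure time,
  shifted inside the trace at the ends (a request at the 300 s mark of
  a 300 s trace averages [299, 300] s).
* Error summaries report mean and sample SD (n−1) of
  (predicted − measured) over subjects; offset correction subtracts
  the unweighted mean of the per-condition means, and corrected values
  are reported to two decimals with ties rounded away from zero
  (binary half-even rounding would turn 0.115 into 0.11).
* The one-way within-subject ANOVA uses the definitional
  sums-of-squares decomposition; Mauchly's W comes from the sample
  covariance of the condition columns in an orthonormal contrast
  basis with the standard χ² approximation, Greenhouse–Geisser ε from
  the eigenvalues of the same matrix, applied to both degrees of
  freedom when Mauchly's p < 0.05.  η² is reported classically
  (SS_effect/SS_total — for this purely within design it coincides
  with generalized η²) alongside partial η².  Pairwise paired t-tests
  are Bonferroni-multiplied by the number of pairs and run on the same
  matrix as the omnibus test.  Missing cells raise; no imputation.

## Synthetic data

The generator fabricates what the real study measured, with ground
truth attached.

**Stimuli.**  Eleven narrowband Gaussian primaries (printed
peaks/FWHMs) plus four phosphor-converted whites modeled as a 450 nm
pump and a broad phosphor band whose peak red-shifts with the nominal
CCT and whose amplitude ratio is root-solved so the channel hits its
CCT label (true measured SPDs are not available).  Weights for a
chromaticity + luminance target are found by non-negative least
squares on the channel tristimulus matrix — the target fixes (X, Y, Z)
exactly, so the solve is deterministic with no seed; infeasible
targets surface as a gamut error.  Achieved tolerance: |Δu′|, |Δv′| ≤
10⁻³ and |ΔL|/L ≤ 0.5%.

**Traces.**  The noise-free diameter is

    d(t) = baseline − A·exp(−t/τ_phasic) − g·M·(1 − exp(−t/τ_redil))

clipped to [1.5, 9] mm, with `M` the stimulus melanopic radiance: a
cone-driven transient recovering with `τ_phasic` (default 1.5 s) and a
melanopsin-weighted sustained constriction approaching steady state
with `τ_redil` (default 30 s — consistent with reports of stabilized
pupils within ~3 min).  On top ride Gaussian noise (SD 0.08 mm),
Poisson-scheduled blinks (0.2 Hz, 150 ms, diameter missing, blink flag
set, low quality) and sparse single-sample ±1 mm spikes with *normal*
quality, visible only to the velocity filter.  Cohorts draw the
baseline per subject (SD 0.75 mm, calibrated to the ±1.5 mm
interpersonal range), add per-presentation jitter (SD 0.3 mm, the
intrapersonal range), and vary the melanopsin gain across subjects
(relative SD 0.3) so that baseline-corrected diameters retain
between-subject variance.  Everything is keyed to one seed and
bit-reproducible.

The generator is a didactic stand-in, not an ipRGC pathway model: it
emulates the *shape* of pupil recordings (phasic + spectrum-dependent
sustained constriction, artifacts, scatter) so that preprocessing and
benchmarking can be validated against exact ground truth.  It does not
model the anchor→stimulus re-adaptation transient (the pupil resets to
baseline at onset), luminance dependence of the dynamics, rod input,
gaze or cognitive effects — so passing pipeline tests demonstrate
correct signal processing and statistics, not physiological fidelity,
and the synthetic benchmark's error magnitudes are not comparable to
measured ones.  For parameter-recovery tests the per-subject gain can
instead be pinned so the designed steady-state diameter equals a
chosen model's prediction exactly.

## Problem sizes

The test suite validates preprocessing recovery and the full
simulate → preprocess → benchmark pipeline at the study's native scale
(20 subjects, 120 Hz, 300 s presentations, 7 stimuli plus interleaved
anchors); unit and property tests use shorter traces (5–60 s) and
reduced rates where the property under test does not depend on scale.

## Known limitations

* Action spectra are analytic approximations (above); absolute α-opic
  values differ from the official tabulations by a few percent.
* The 2700 K synthetic white sits ≈0.048 below the locus in duv —
  two Gaussians are a crude stand-in for a warm-white SPD.
* The velocity filter's percentile thresholds make its effect depend
  on recording length (a fixed 0.007% tail of more samples removes
  more samples).  This mirrors the reference recipe.
* `rm_anova` covers the one-way within-subject design only.
* Mauchly's p uses the first-order χ² approximation; implementations
  carrying the second-order Box term differ in the third decimal of p
  (the W statistic itself agrees to machine precision).
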