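# Methods

This note documents the models, conventions and numerical choices behind
`micropat`, and what the synthetic validation does and does not show about
real data.

## Measurement model

All metrics are ratios or differences of background-subtracted ROI means.
The camera background is a single scalar pair (mean, variance) obtained by
pooling a dark-frame stack: per-pixel temporal mean and unbiased variance
across frames, then averaged over pixels. This matches how the metrics use
it — as the floor common to every ROI — and deliberately ignores per-pixel
fixed-pattern structure (an sCMOS subtlety outside this package's scope).
Passivated, never-exposed coverslip regions are treated as equivalent to
the camera background, which holds when the passivation layer is
non-autofluorescent; the `nonspecific_binding` metric exists precisely to
measure the residue above that floor.

ROI statistics use the arithmetic mean and the unbiased (n−1) sample
variance. A single-pixel ROI has variance 0 and carries an explicit
`degenerate` flag rather than NaN. Coordinates are pixel-centered, 0-based,
row-major; masks are inclusive pixel sets.

**Homogeneity** divides the background-corrected mean by the
background-corrected *variance*, giving ADU⁻¹. A variance-denominator index
is not scale-free, which is why the package also exposes
`homogeneity_sd` (mean over SD, an inverse coefficient of variation) under
its own name; the two are never substituted for one another, and all
validation targets the variance form.

**Unmeasurable results.** Whenever a denominator is at or below the camera
floor (off-pattern mean, outer-ROI signal, variance difference), the
function returns a typed `Unmeasurable(reason)` object that is falsy and
excluded explicitly by aggregation code. Nothing is clipped to zero or
reported as ±inf, so downstream statistics cannot silently absorb
nonsense values.

**Off-pattern ROI placement.** When the user does not supply an off-pattern
ROI, the pattern mask itself is translated to the nearest position whose
footprint clears all patterns dilated by a 3 px margin — "adjacent ROI of
identical size" made deterministic. Candidate translations are ranked by
Euclidean length with ties broken by angle from east, counterclockwise;
collision testing is a single FFT cross-correlation of the exclusion map
with the ROI footprint. Because the ROI is a translate of the pattern ROI,
it has identical size and shape by construction.

**Nonspecific binding** requires the off-pattern measurement to be
congruent with the intended-pattern ROI so illumination inhomogeneity
cancels. Two modes are accepted: a second acquisition of an unpatterned
sample region, on which the intended mask is reused verbatim (same position
in the field of view), or an ROI in the same image that must be an exact
pixelwise translation of the intended mask.

**Enrichment indices.** Four variants share one algebraic skeleton,
differing only in the correction term: off-pattern background (synthetic
receptors), cell-free counterpart ROIs (endogenous receptors, correcting
ligand bleed-through), or the ROI's own pre-landing value (time-resolved
recruitment). The raw signal increase (inner − inner₀) − (outer − outer₀)
is additionally invariant to any global additive drift, which makes it the
stable choice at low signal; the fold variant is not, and the test suite
pins that behavioral contrast. Cell-free ROI pairing is explicit user
input; the package does not detect cells. The time course uses a single
frame per time point by default (window size configurable), with t₀ the
last frame before the cell lands (user-overridable).

## Segmentation and the diameter gate

Patterns are detected from an anchor-fluorescence channel: Gaussian smooth
(σ = 1 px), Otsu threshold (or a fixed threshold for full
reproducibility), hole filling, removal of components below a minimum
area, 8-connected labeling. Equivalent diameter is 2·√(area/π); the
adhesion analysis keeps labels with equivalent diameter in [20, 40] µm,
inclusive. Manual ROIs (label TIFF or JSON polygons) bypass segmentation
entirely and are first-class inputs throughout.

## Adhesion metrics

A cell is on-pattern iff its centroid lies in a labeled pixel; an
any-overlap rule (centroid within one cell radius of a labeled pixel) is
available but not the default, since the centroid rule is unambiguous for
cells comparable in size to the patterns. Normalized nonspecific adhesion
is computed as 100·d_off/(d_on + d_off) — the only reading of the printed
formula that keeps the quantity a percentage in [0, 100], with 50%
meaning pattern-indifferent adhesion.

## Gliding-assay analysis

Movies are max-projected in time to reveal swept paths; kymographs sample
the movie along a polyline at 1 px arc-length steps (bilinear
interpolation), averaging across an odd number of perpendicular offsets.
The filament is localized per frame by an intensity-weighted centroid
inside a tracking window (default 25 px half-width, seeded by the global
maximum) after subtracting the column median; the window prevents
clipped-noise bins far along the path from leveraging the centroid. A
frame whose windowed peak is below 5× the column's robust noise rejects
the trace as unlocalizable rather than returning a silent garbage path.

Run/pause segmentation uses an explicit, recorded criterion: an interval
is paused when its |speed| falls below max(20% of the trace's median
moving speed, an absolute floor of 0.5 px/frame) for at least 2
consecutive frames. The threshold is estimated in two passes (all frames,
then moving frames only); the absolute floor makes fully stationary traces
classify as 100% paused instead of chasing localization noise. Mean speed
is computed over moving intervals only and is undefined (flagged, not 0)
for a fully paused trace. A trace is motile iff its net displacement is
≥ 1 µm; a manual-override list stands in for by-eye classification where
users want it. All three parameters are configurable and echoed in the
outputs. Group statistics are reported as mean ± SEM with n; empty groups
report an undefined (NaN) fraction, never 0.

## Synthetic data generator

The generator emulates the statistical structure the metrics assume, with
closed-form expected values computed from the generating parameters before
any noise is drawn:

- **Camera**: constant offset + Gaussian read noise, Poisson shot noise on
  signal×gain — the minimal sCMOS-like model consistent with scalar dark
  statistics. Defaults: offset 100 ADU, read noise 2 ADU, gain
  1 ADU/photon; conventional values for a back-illuminated sCMOS, chosen
  here as defaults (they are configuration, not measurements).
- **Patterns**: disks/stripes/annuli/rectangles of specified mean photon
  rate. Within-pattern variation is a low-pass-filtered (σ = 3 px)
  Gaussian field renormalized over the pattern pixels to the requested CV,
  so homogeneity is controlled independently of the mean. Expected
  homogeneity is g·µ/(g·µ + (g·cv·µ)²), strictly decreasing in cv.
  Off-pattern adsorption is a spatially uniform Σ on_mean·off_fraction.
- **Multiplexing**: channel c deposits on_mean·crosstalk[c, i] on pattern
  i, with the intended entry fixed at 1; injected crosstalk in the
  0–3% range mirrors the regime relevant for sequential patterning.
- **Filaments**: Gaussian-profile line segments (σ = 1 px) advancing along
  polyline paths; sub-pixel positions are rendered by analytic profile
  evaluation, never nearest-pixel stamping. Pauses are emitted as blocks of
  ≥ 3 frames whose total matches round((1−duty)·n): i.i.d. per-frame pauses
  would be mostly single frames, which no run-length pause detector can
  see, whereas real pauses span multiple frames. The realized per-frame
  schedule is recorded in the ground truth and recovery is judged against
  it. Off-pattern filaments never move, emulating surface-stuck
  microtubules outside the motor pattern.
- **Cells**: disks placed at Poisson(density × area) counts per region,
  uniform within region, rejected to non-overlap (densities beyond a 0.6
  packing fraction are refused).

All randomness flows from one `numpy.random.Generator` seeded explicitly;
there is no global random state, and fixed seeds reproduce outputs bit for
bit.

### Problem sizes used in validation

Validation simulations use fields of 128×128–64×1000 px at 0.11 µm/px
(0.5 µm/px for segmentation fixtures so 50 µm disks fit a small field),
50 fields per recovery condition, 200-frame movies at 0.5 s intervals, and
25–30 adhesion fields — sizes at which the estimators' sampling error is
well below the tolerances being checked while a full run stays fast enough
for routine development.

### What passing tests do and do not show

The generator validates the *estimators*: that each formula, applied to
images with known generating parameters, recovers those parameters at
realistic SNR. It does not model optical PSF blur, TIRF evanescent-field
depth, photobleaching, illumination inhomogeneity (beyond the
matched-position ROI rule that corrects it), per-pixel sCMOS gain/offset
variation, or biological variability in cells and filaments. Passing
recovery tests therefore says the measurement code is correct and
unbiased under the stated noise model — not that any particular biological
conclusion follows from a given dataset.

## Known limitations

- Homogeneity's variance denominator makes its numeric value depend on the
  intensity scale; compare it only within one acquisition setting (the
  SD variant exists for cross-setting comparisons).
- The kymograph tracer assumes one dominant filament per path; crossing
  filaments will corrupt each other's traces.
- The pause criterion is a documented stand-in for unpublished plugin
  defaults used in the field, not a reconstruction of them.
- Statistical hypothesis testing across conditions (ANOVA, t tests) is out
  of scope; the package emits tidy per-object tables for downstream tools.
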