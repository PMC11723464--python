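# Methods

This note documents the models and conventions behind `hazelhealth`: the
segmentation and aggregation rules, the synthetic-orchard generator and
its calibration, the classifier protocol, numerical choices, and the
limits of what the synthetic experiments demonstrate.

## Imagery model and conventions

All imagery is handled as a `BandStack`: co-registered 2-D reflectance
grids for GREEN, RED, RED_EDGE (≈730 nm) and NIR (≈840 nm), float64 in
[0, 1] (BLUE is accepted but unused). Integer digital numbers are divided
by their dtype's full scale at load time; out-of-range or non-finite
pixels are clipped and counted in the stack's provenance. Normalizing to
reflectance matters for exactly one index: every index except SAVI is
invariant under a common band rescaling, but SAVI's additive soil factor
L is defined on reflectance.

Pixel coordinates are row-major, 0-based, origin top-left; all windows
are half-open `[r0, r1) × [c0, c1)`, which makes the slicing arithmetic
exact (windows tile the frame, asserted in tests). Imagery round-trips
through multiband TIFF with band names and ground sample distance stored
as JSON in the TIFF description; 16-bit output bounds the round-trip
error by one quantization step (1/65535).

## Segmentation and slicing

* **Geometric crop** — square of side `round(spacing_m·100/gsd)` px
  centred on the trunk (400 px at 4 m and 1 cm/px); off-scene area is
  zero-padded with a warning. Intended for mature orchards where canopies
  overlap and spectral separation of neighbours is impossible.
* **Soil exclusion** — canopy = pixels with NDVI ≥ 0.2. The rule is kept
  as strict-less-than exclusion, so a pixel exactly at the threshold
  counts as canopy. Soil sits well below this cut (bare-soil NDVI is
  ≈0.05–0.15), vigorous canopy well above 0.3.
* **Contour hierarchy** — on the binary mask, any contour strictly
  contained inside another (hole borders, islands inside holes) is
  removed and the retained outer contours are filled. On a raster mask
  this is exactly per-component hole filling, implemented with the
  background-connectivity dual (8-connected foreground, 4-connected
  holes). The operation is idempotent.
* **Slicing** — grid boundaries at `floor(i·dim/3)`, remainder absorbed
  by the last row/column, so cell sides differ by at most 1 px. At the
  default geometry a cell is 1.33 m × 1.33 m ≈ 1.78 m². Cells with canopy
  fraction < 0.5 ("mostly soil") are dropped before any statistics;
  0.5 is a configurable convention — no principled value exists.
* **Aggregation ambiguity** — whether slice VI means should run over all
  pixels or canopy pixels only is genuinely open; both modes exist
  (`VIConfig.use_mask`), canopy-only is the default since soil pixels
  carry no plant signal.

## Vegetation indices

Nine indices (formulas in the README). Numerical conventions:

* A pixel is invalid for an index when the denominator magnitude is below
  `epsilon` (default 1e-9). Invalid pixels are dropped from the slice
  mean, never clamped — clamping biases the unbounded ratio indices — and
  the valid-pixel count is reported alongside every mean so the effect is
  auditable.
* TCARI appears in the literature in slightly different typesettings;
  both `3[(RE−R) − 0.2(RE−G)(RE/R)]` (default, `standard`) and
  `3[(RE−R) − 0.2(R−G)(RE/R)]` (`paper_literal`) are implemented. TCARI
  is never selected on calibrated data, so the choice does not propagate.
* SAVI's L defaults to 0.5 (common practice; 0 recovers NDVI exactly —
  tested to 1e-12 — and 1 suits sparse canopies).

**Selection.** The field practice this package systematizes judged class
separation from boxplots; here it is quantified as Cohen's d with pooled
SD on per-slice means, selecting |d| ≥ 0.5. The 0.5 threshold is a
stand-in for a visual judgement, not an estimated quantity. One coupling
rule is applied on top: NDVI is excluded whenever SAVI is, because SAVI
is NDVI plus a soil-brightness correction and cannot fail while NDVI
carries signal.

## Synthetic orchard generator

The generator exists because the field imagery this package's design is
based on is unreleased. It must support two things: (i) exact ground
truth for unit/property tests of every stage, and (ii) a slice-level VI
statistics profile matching the empirically observed pattern — GNDVI,
GCI, NDREI, NRI, GI discriminative; NDVI, SAVI, RECI, TCARI not.

**Geometry.** One 400×400 px frame per plant (4 m cell, 1 cm/px). The
canopy is a union of 5–9 random discs near the frame centre
(`canopy_radius_m` = 1.7 ± 0.15 m — bushy hazelnuts nearly fill the
planting cell). Unhealthy quadrants receive one compact connected patch
covering ~60 % (±20 %) of the quadrant's canopy, mimicking localized
wilting/branch collapse; quadrant ground-truth labels are always
consistent with rendered pixels (a labeled quadrant whose canopy the
discs missed is demoted to healthy).

**Spectra.** Default class means (G, R, RE, NIR):

| class     | GREEN | RED  | RED_EDGE | NIR  | NDVI  |
|-----------|-------|------|----------|------|-------|
| soil      | 0.18  | 0.22 | 0.24     | 0.25 | 0.064 |
| healthy   | 0.10  | 0.06 | 0.30     | 0.50 | 0.786 |
| unhealthy | 0.15  | 0.06 | 0.36     | 0.50 | 0.786 |

Stress is rendered as *chlorophyll loss with preserved canopy structure*:
GREEN and the red-edge shoulder rise, RED and NIR are untouched. This is
the one spectral regime consistent with the observed index pattern — any
appreciable NIR drop would make NDVI and (more strongly) SAVI separate
the classes at slice level, which is not what field data showed for this
crop. These numbers are calibration defaults, not measured signatures.

**Variance model.** Three nested scales:

1. *Between plants*: multiplicative log-normal band factors (log-sd
   G 0.04, R 0.04, RE 0.04, NIR 0.06), shared by all pixels of a plant so
   within-plant class contrast is preserved. These dominate slice-level
   dispersion and set the effect sizes of the bounded indices.
2. *Per pixel*: independent Gaussian noise (canopy sd G 0.015, R 0.012,
   RE 0.10, NIR 0.025; soil 0.015). The wide RED_EDGE sd encodes the
   strong structural variability of the red-edge shoulder.
3. *Contamination*: a per-plant fraction of canopy pixels (expectation
   0.08, log-normally distributed across plants) drawn with ×3 sd around
   the canopy-wide healthy mean — optical artifacts (specular glints,
   shadow holes, sub-pixel soil mixing) that look the same on healthy and
   stressed foliage, hence class-independent by construction.

Reflectance is clipped to [0.002, 1]; calibrated reflectance never
reaches exactly zero, and the positive floor caps ratio-index spikes at
a finite magnitude.

**Why this decouples RECI from NDREI.** NDREI and RECI are both monotone
functions of x = NIR/RE at the pixel level, yet one must be informative
and the other not. The decoupling is differential robustness, not
information content: contaminated red-edge pixels regularly reach the
reflectance floor, where RECI = NIR/RE − 1 spikes to order 10²–10³ while
NDREI saturates below 1. Because the contaminated share varies between
plants, slice-mean RECI acquires a large, heavy-tailed, class-independent
variance component that swamps its class gap (|d| stays below ~0.4),
while NDREI's bounded form shrugs the same pixels off (|d| above 0.8).
This mirrors the field experience that unbounded ratio indices are
fragile under denominator noise. The same mechanism leaves GCI and GI
usable because GREEN and RED have small noise scales relative to their
means.

**Calibration contract** (executable, `tests/test_acceptance.py`): on the
default dataset (≥200 slices per class, seed 0) the slice-level effect
sizes satisfy |d| ≥ 0.8 for GNDVI, GCI, NDREI, NRI, GI and |d| ≤ 0.4 for
NDVI, SAVI, RECI, TCARI, with healthy higher on GNDVI/GCI/NDREI and lower
on NRI/GI; the d ≥ 0.5 selection then recovers exactly
{GNDVI, GCI, NDREI, NRI, GI}. Simulation during design showed the margins
hold across seeds (weak max |d| ≈ 0.36, strong min |d| ≈ 0.9).

**Prevalence.** Quadrant labels are i.i.d. Bernoulli(p); 10 % of plants
are instead forced to exactly one unhealthy quadrant (localized early
symptoms occur at about that rate in the field). The three-time-point
scenario uses p = 1/(1+r) for target healthy:unhealthy ratios
r = 2.28, 0.92, 0.39 — the seasonal drift from early to late season.

**What the generator does *not* emulate** — and therefore what passing
tests do not show about real data: illumination gradients and shadows,
spatially correlated noise, mixed canopy boundaries between neighbouring
trees, registration error between bands, pathogen-specific spectral
signatures, and the hard class overlap of real orchards. Synthetic
classification accuracies (≈0.95+) say the pipeline is correct and the
calibrated separations are learnable; they say nothing about achievable
field accuracy, which was ≈0.65 in the study this emulates.

## Classification protocol

Stratified 80–20 split (per-class test counts exact to ±1), fixed
hyperparameters as in the README, 5-fold stratified cross-validation
reported alongside the hold-out metrics since it is ambiguous which a
field study's headline numbers came from. Optional random search
(20 seeded draws, spaces documented in `classify.SEARCH_SPACES`) tunes by
CV accuracy then refits; off by default. Features enter raw — the
protocol this follows mentions no standardization — with a `standardize`
flag available because KNN is scale-sensitive. The false-negative rate
uses the whole test set as denominator (132/823 ≈ 16 % style accounting),
not just the positives.

## Reproducibility and problem sizes

Every stochastic stage derives its seed from one global seed; reruns are
bit-identical (tested). Rendered plants are ~5 MB each, so dataset
iteration is lazy (`iter_dataset`); label streams can be sampled without
rendering (`sample_quadrant_labels`) for large-n prevalence statistics.
The test suite uses 30–90-plant orchards and the acceptance script
90–100-plant studies with 2000-plant label-only sampling — sizes chosen
so statistics are stable at interactive runtimes; all scale linearly in
`n_plants`.

## Known limitations

* The canopy-segmentation path assumes a reasonably centred single plant
  per frame; there is no automatic trunk detection.
* Cohen's d assumes roughly symmetric within-class distributions; for
  RECI the heavy tail makes d conservative, which is acceptable here
  because RECI only needs to be recognized as non-discriminative.
* The spectral calibration is one consistent explanation of the observed
  index pattern, not an identified physical model; alternative regimes
  (e.g. partial structural decline plus stronger noise) could produce
  the same ranking.
* No radiometric calibration, orthomosaicking or georeferencing: inputs
  are assumed to be reflectance already.
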