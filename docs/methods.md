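# Methods

This note documents the models, parameter choices and known limits of
`camikit`'s isolation-planning pipeline. Everything quantitative stated
here is recomputed by the test suite or `scripts/acceptance.py`.

## Synthetic slide model

The generator is the package's ground-truth oracle; its defaults define
the canonical study conditions used throughout the tests.

* **Field**: 1024 × 1024 px at 0.65 µm/px (≈ 666 × 666 µm), dark
  background at 100 counts, written as 16-bit TIFF.
* **Nuclei**: `n_nuclei = 200` ellipses, semi-minor axis 3.2–4.6 µm,
  aspect ratio 1.0–1.5, random orientation, peak amplitude 600 counts
  ±15%. The boundary is Gaussian-tapered (width 10% of the radius) —
  a reasonable stand-in for chromatin-stained nuclei imaged slightly
  out of perfect focus. The binary ground-truth mask is the ellipse at
  the taper midpoint.
* **Overlap**: `overlap_fraction = 0.2` of nuclei are placed as pairs
  with center distance uniform in 0.8–1.2 × the sum of the semi-minor
  axes: overlap is real (intensities merge into one component) but
  each member keeps its own wavelet response peak. All other nuclei
  keep ≥ 1.2 × the sum of their radii apart.
* **Phenotypes**: two classes split 50/50. "foci" nuclei carry 5–10
  punctate marker spots (σ = 1.6 px, amplitude ≈ the marker scale 500)
  on a dim base; "homogeneous" nuclei are filled uniformly; a
  "negative" profile (background only) is available for three-class
  scenarios.
* **Shading**: a smooth tilted-bowl multiplicative gain with relative
  amplitude `illumination_strength = 0.3`, or any user-supplied
  polynomial in normalized coordinates. The true field is stored.
* **Noise**: additive Gaussian, `noise_sd = 8` counts (≈ 1.3% of the
  nuclear peak signal).
* **Landmark**: an asymmetric "L" glyph (full-height bar, shorter
  foot, detached dot) of 50 × 50 µm, rasterised at an integer pixel
  corner; the ground truth records the rendered center. The glyph's
  four right-angle rotations are mutually distinguishable (pairwise
  normalized correlation < 0.9), which is what makes orientation
  disambiguation testable.

What the generator does **not** emulate: tissue autofluorescence and
texture, focus gradients, photobleaching, z-structure, debris, and
segmentation-relevant pathology (folds, tears). Passing tests therefore
demonstrate algorithmic correctness under controlled conditions, not
performance on any particular tissue.

## Illumination correction

Model: `observed = gain(x, y) · clean + offset(x, y)`. The gain is a
degree-2 (configurable) 2-D polynomial fitted to the per-pixel 25%
quantile of the image stack — in a sparse fluorescence scene the low
quantile tracks `background × gain` — by L-BFGS-B minimisation of a
Huber loss (δ = 1.345 robust sigmas, the classical 95%-efficiency
choice), initialised from ordinary least squares on a ≤ 20 000-pixel
grid subsample. The fitted surface is floored at a small positive value
and normalised to mean 1, so corrected intensities stay on the input
scale. The offset surface is zero by default: the generator (like
dark-subtracted camera data) is purely multiplicative; a constant dark
level can be supplied per channel. Correction of a flat stack is
therefore an exact no-op. Fitting requires ≥ 2 images — a single image
cannot separate shading from content, and the driver must disable the
stage explicitly rather than have it silently skipped. Correction is
per-channel (shading is wavelength-dependent).

Measured on planted fields: polynomial gains of degree ≤ 2 at low noise
are recovered to well under 1% per-pixel error; one saturated blob in
one stack image moves the fit by < 5% (the quantile + Huber combination
absorbs it); refitting on corrected images returns gain ≈ 1 within 5%.

## Segmentation

**Seeding.** B3-spline à trous (stationary) wavelet transform, kernel
[1, 4, 6, 4, 1]/16 with dilated holes. Detail planes at scales {3, 4}
are hard-thresholded at `k_sigma = 3` × a MAD-based noise estimate
(MAD/0.6745) of each plane; the multiscale support is the intersection
of the thresholded planes, pruned of specks < 4 px. Seeds are the local
maxima (minimum separation 6 px) of the summed, lightly smoothed
(σ = 1.5 px) wavelet response inside the support. Scales {3, 4} match
the 10–18 px nuclei at this pixel size; maxima rather than one centroid
per support component are used because the supports of touching nuclei
merge into a single component while each nucleus retains its own
response peak — the property the overlap splitter depends on. Seeding
is invariant to adding a constant to the image (the wavelet planes have
zero mean response to it), and a constant image yields no seeds because
the threshold comparison is strict.

**Foreground.** Otsu thresholds computed in 128-px blocks and
bilinearly interpolated between block centers; blocks whose dynamic
range falls below 25% of the global range (no nuclei present) fall back
to the global Otsu value so background noise is never split. Holes are
filled, a 3×3 opening removes specks, and components claimed by no seed
are dropped into diagnostics.

**Overlap splitting.** Components holding ≥ 2 seeds are partitioned by
seeded watershed on the inverted Euclidean distance transform,
restricted to the component — the split follows the shape neck, which
is the robust evidence when two flat-topped intensity profiles merge
into a plateau (an intensity-based landscape splits such plateaus
arbitrarily; the distance landscape recovered ~6% more planted nuclei
in development measurements). A split is kept only if the boundary
crosses a genuine neck: if the distance transform on the shared
boundary reaches ≥ 90% of the shallower lobe's peak distance, the
"lobes" are one round object (e.g. twin response peaks on a symmetric
plateau) and are re-merged. The partition is exact: region areas sum to
the component area, each region is connected and contains its seed.

Conversely, the dimmer member of a heavily overlapping pair sometimes
produces no wavelet peak at all. Components claimed by a single seed
therefore receive *rescue markers* at strong distance-transform lobes
(≥ 55% of the component's maximum depth, ≥ 7 px from the seed and each
other) before splitting; the neck criterion above re-merges any rescue
candidate that does not sit behind a genuine neck, so offering them is
safe for round or elongated single nuclei.

**Quality flags.** Minimum segment area 60 px² (the smallest credible
nucleus under the study conditions is ≈ 75 px²); border-touching
segments are kept but excluded from isolation (a cut cell must lie
fully on the slide).

**Boundary polygons.** Marching-squares contour of the padded mask at
level 0.5, outer ring only (holes are ignored), Douglas–Peucker
simplified at 0.4 px; polygon area agrees with the pixel count to ~5%.

Measured under the canonical conditions (200 nuclei, 20% overlapping,
default noise and shading, after correction): ≥ 90% of planted nuclei
matched at IoU ≥ 0.5 with ≤ 10% spurious segments, across independent
seeds.

## Feature registry (92 measurements)

Version 1.0, frozen and asserted at import:
2 channels × (14 intensity + 26 texture) + 12 shape = 92.

* Intensity (per channel): mean, median, std, MAD, min, max,
  integrated, quantiles 10/25/75/90, IQR, edge mean, edge/interior
  ratio (interior = mask eroded 2 px).
* Texture (per channel): the 13 classic co-occurrence statistics
  (angular second moment, contrast, correlation, variance, inverse
  difference moment, sum average/variance/entropy, entropy, difference
  variance/entropy, and both information measures of correlation),
  each summarised as mean and range over the four GLCM directions at
  unit offset. Intensities are quantized to 32 gray levels inside the
  mask; the background row/column of the co-occurrence matrix is
  removed before normalisation. Degenerate statistics (zero marginal
  variance or entropy) are defined as 0 so vectors are always finite.
* Shape: area, perimeter, form factor 4πA/P², eccentricity, solidity,
  extent, equivalent diameter, major/minor axis, orientation, aspect
  ratio, and the coefficient of variation of the boundary radius.

Features are computed on bounding-box crops (hence exactly translation
invariant) of illumination-corrected images. Shape features are
invariant to intensity rescaling; mean/integrated intensities are
equivariant. Both channels contribute intensity and texture blocks —
the marker channel carries the phenotype signal, the nuclear channel
normalises for staining variation.

## Classification and selection

Candidate algorithms (config-overridable): random forest (200 trees),
logistic regression, 5-NN and an SVM with calibrated probabilities, the
last three behind a standardising scaler. Stratified k-fold
cross-validation (k = 10, shuffled with a recorded seed) scores each;
the best is refit on every annotation. Classes thinner than k raise an
error telling the user to reduce k or annotate more. Confidence is the
winning class's calibrated membership score; exact ties are broken by
class-name order and flagged ambiguous. A reserved `discard` class is
trainable but never selectable. Ranking is per class by descending
confidence with a deterministic (confidence, slide, label) tie-break;
the default quota is 200 cells per class, and under-quota classes
return everything with a recorded shortfall. On the canonical two-class
synthetic conditions the chosen model's 10-fold CV accuracy exceeds
0.91 by a wide margin — a floor, not a claim about any real dataset.

## Cutting contours and registration

The cutting contour is the nucleus polygon dilated outward by 3 µm
(shapely round-joined buffer, 32 segments per quadrant) in physical
units, then simplified to ≤ 64 vertices under two constraints: the
contour still contains the nucleus and its clearance never drops more
than 0.2 µm below the ring distance. Contours leaving the imaged area
are flagged clipped; contours intersecting another nucleus mask or
another selected contour are flagged as collisions (symmetrically) and
excluded from the default export but kept in diagnostics.

Landmark detection: normalized cross-correlation against the stored
template at all four right-angle rotations, sub-pixel refinement by a
1-D quadratic fit per axis around the peak, acceptance threshold 0.6.
The coordinate relation between the two instruments is the fixed axis
swap plus translation given in the README; it is implemented exactly as
printed (a `swap_axes=False` switch exists for instruments sharing
conventions) and is an isometry, so registered contours preserve area
and vertex order to machine precision. If the two instruments detect
different landmark orientations, registration refuses rather than
silently rotating — rotational misalignment is out of scope and is the
user's cue to re-mount the slide or etch additional landmarks.

## Pipeline and export

One YAML config with a single global seed drives
illumination → landmark detection → segmentation → features →
training/selection → prediction → ranking → contours → registration →
export; every stage writes its artifact and appends to a structured
log, so each exported cell has a complete provenance chain. In
synthetic mode the training annotations are sampled from the planted
ground truth (balanced, 40 per class by default) — a stand-in for
interactive annotation. The export dialect (manifest CSV, per-cell
JSON contour vertex lists in target-frame µm at 10⁻⁶ µm precision,
PNG snapshot crops) is this package's own documented format.

## Problem sizes and determinism

The canonical conditions (1024² px, 200 nuclei, 3-slide stacks) are
used for the per-stage guarantees; the end-to-end reproducibility check
runs the full pipeline twice on a 2-slide, 512² px, 60-nucleus
configuration — the same code path at a size chosen to keep the whole
suite pleasant to run — and requires byte-identical export manifests.
All randomness flows from explicit integer seeds; there is no hidden
global RNG state.

## Known limitations

* The illumination model is a deliberate low-order simplification of
  full retrospective multi-image correction; strongly non-polynomial
  shading (dust shadows, interference fringes) is out of reach.
* The distance-transform splitter assumes roughly convex nuclei; it
  will bisect genuinely dumbbell-shaped single nuclei.
* Haralick features depend on the 32-level quantization; vectors are
  comparable only within a registry version.
* The classifier floor is established on synthetic conditions whose
  class contrast is generous; real annotation noise and class
  imbalance will lower it.
* Registration handles translation and 90° orientation only — by
  design, angular misalignment is refused, not corrected.
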