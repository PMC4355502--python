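# Methods

This note records the model, the parameter choices that matter, what the
synthetic phantom does and does not emulate, and the numerical decisions made
where the method left the design open.

## Pipeline model and assumptions

The segmenter assumes a single frontal (PA or AP) grayscale chest radiograph
in which, after polarity normalization, the lungs are the darkest large
structures and the mediastinum/spine column is bright. It is rule-based and
unsupervised: no training images, no shape model. Its stages and working
resolutions:

| stage | resolution | output |
|---|---|---|
| pre-processing (invert / crop / stretch) | native | standardized image |
| oriented Gaussian-derivative bank + auto-threshold + rules | 512×512 | L_outline |
| HFEF + blur + Otsu + convex hull + morphology | 256×256 | L_mask |
| FCM (n=8) cluster combination | 256×256 | L_final (upsampled to native) |

Resampling policy: anti-aliased bilinear for intensities, 2×2 max-pooling for
the outline (thin borders must survive), nearest neighbor for masks.

### Pre-processing

Three machine profiles: `standard` (no special handling), `background` (dark
detector border with printed labels → crop), `inverted_background` (invert,
then crop). `auto` resolves the profile with two statistics: (i) *inversion*
— median of the central mediastinum column strip (cols 45–55%, rows 20–80%)
vs the median of the lung-flank strips; in normal polarity the mediastinum is
brighter. This anatomy-based test is deliberately interior to the chest, so
detector borders cannot bias it; a border-vs-center comparison fails on chest
images because the center quarter is dominated by the dark lungs. (ii)
*background* — a 10-px frame-ring median below half the central-quarter
median flags a padded detector border.

Cropping: Otsu on the intensity image (bright class = body), dilation by a
disk of 1% of the smaller image dimension (≥ 3 px) to merge faint edges,
keep the largest component plus components overlapping its bounding box
(isolated printed labels are dropped), and crop to the bounding box of the
**undilated** foreground of the kept components. Using the undilated support
matters: including the dilation ring leaks a margin of dark border into the
frame and shifts the contrast-stretch percentiles, which measurably changes
every downstream stage.

Contrast stretch (2% total, 1% per tail, saturating) is applied to **all**
profiles, after cropping. The stretch is monotone, so it cannot affect the
Otsu-based crop; applying it uniformly and post-crop makes the three machine
profiles of the same exposure converge to the same working image — on
phantoms they produce bit-identical final masks.

### Gaussian-derivative bank

First-order derivative of a unit-normalized 2-D Gaussian, σ = 3 px, truncated
at 4σ (25×25), replicate borders. Orientation θ is measured from the +x
(column) axis with y down the rows, and the response is the *negative*
directional derivative of the smoothed image, so a bright→dark transition
along +θ responds positively; θ = 0° then highlights the outer right-lung
and inner left-lung borders and θ = 90° the hemidiaphragm tops. The bank is
computed by cos/sin steering of the two axis-aligned separable responses,
which is exact for first-order filters; tests verify agreement with direct
oriented convolution to 1e-6 relative.

Before threshold selection, responses are scaled by 4095 (the 12-bit dynamic
range typical of radiograph DICOMs). The threshold histogram counts *integer*
values, so its resolution is fixed by the absolute response scale; with [0,1]
images all responses would round to zero. The scale is configurable
(`response_scale`) and is the package's representation of working directly on
12-bit intensities.

### Automatic threshold

As described in the README: histogram numbers → peaks (strict local maxima
above the mean, plateau = one peak at its first index) → chosen peaks
(strictly after the global maximum, height in [3, 8]·mph) → threshold =
largest chosen-peak value. Rounding is half-away-from-zero. Only the positive
tail is thresholded (mask = response ≥ T); negative-gradient structure is
recovered by the opposite orientation via antisymmetry. When no peak
qualifies — a real failure mode on smooth-tailed histograms — the fallback is
the 98th percentile of the strictly positive rounded values; an all-negative
response contributes an empty mask. The whole stage is validated against an
independent straight-line reimplementation on 1,000 random responses.

### Rule system

All rules are pure 8-connected component filters; comparisons follow the
rule wording exactly ("less than" strict, "at most"/"at least" inclusive),
and "located between X% and Y%" means every pixel of the component lies in
the band. Each boundary is unit-tested at the pixel that straddles it (e.g.
a 1,310 px component is removed at 512² by the 0.5% rule, a 1,311 px one is
kept). The body-artifact area floor is 2.5% of the image size (an alternative
reading of 25% would make the rule nearly inert). Radiological convention
throughout: the patient's right lung occupies low column indices.

### Outline filling

HFEF uses H(u,v) = k1 + k2·H_hp with a Gaussian high-pass, k1 = 0.5,
k2 = 1.5, D0 = 25% of the image width, followed by full-range histogram
equalization — textbook defaults, exposed in config, since only the filter
family is prescribed. The 32×32, σ = 10 blur kernel is even-sized, implying
a half-pixel grid offset; this is one consistent sub-pixel shift shared by
everything downstream and is negligible against the σ = 10 smoothing. Otsu
keeps the *darker* class (lungs, after polarity normalization). The convex
hull is computed by an exact integer monotone-chain on pixel centers and
rasterized with integer half-plane tests, so hull vertices and the hull mask
match a brute-force gift-wrapping oracle exactly; `convex_hull_image`-style
corner-offset heuristics would not. `build_mask` uses a disk of 2% of the
image width for the dilate/fill/erode closing and drops regions below 1% of
the image area (the outline-stage 0.5% rule concerns thin outline fragments;
the filled-mask stage works on solid regions, so a slightly larger floor is
used — both configurable).

### FCM refinement

Standard FCM on scalar intensities (fuzzifier m = 2, Euclidean distance,
tol = 1e-4 relative centroid shift, ≤ 200 iterations), on the full 256×256
masked image including the zeroed background, so the lowest-centroid cluster
c1 is the background. Initialization: evenly spaced quantiles of the *unique*
intensity values, jittered deterministically by the seed. Quantiles of the
raw distribution would place most centroids exactly at zero (the background
spike holds ~70% of the mass) and create duplicate clusters; unique-value
quantiles spread the centroids over the intensity range regardless of mass.
Convergence (memberships normalized, objective non-increasing) is verified
numerically over 50 initializations.

Cluster combination choices, where the recipe was open:

* c5 consolidation ("minimum lung region"): closing with a disk of **6% of
  the image width** (≈ 15 px at 256). The mid-intensity cluster appears as
  vessel/rib-shadow speckle spread through the lung fields; the closing
  radius is sized to bridge the spacing of those shadows so the speckle
  consolidates into a solid region. Then hole filling, two largest
  components, one dilation (disk 1).
* The gate is clipped to L_mask: refinement only trims the estimated mask,
  never grows it (final ⊆ L_mask holds exactly, verified in tests).
* c6 erosion and the final opening use a disk of radius 1 at 256×256.
* The central discard band for c6–c8 is 40–60% of the *working (cropped)*
  frame width.
* `finalize` declines the refinement — returning L_mask with a warning —
  when the combined clusters produce a mask below **half** of the L_mask
  area (or an empty one). The refinement is a trimming step; a collapse of
  more than half signals the intensity clusters failed to line up with the
  lung fields, and keeping L_mask is then strictly better. This implements
  the invariant that refinement never catastrophically degrades the mask.

### Metrics

accuracy, overlap = TP/(TP+FP+FN), sensitivity, specificity, precision,
F = 2PR/(P+R). Zero-denominator ratios report 0 with a `degenerate` flag.
Batch std is the sample (n−1) standard deviation; a single case reports 0.
Evaluation is whole-image (both lungs together).

## Synthetic phantom

The generator emulates the structures that drive each pipeline stage, with
ground truth defined analytically (lung ellipses minus the region below the
diaphragm domes):

* two tilted elliptical lung fields (dark) on a soft-tissue thorax filling
  the frame; bright mediastinum band with a Gaussian column profile and a
  vertical ramp (narrow superior mediastinum / tracheal air column);
* hilar vascular gradient plus band-limited vessel texture inside the lungs —
  this produces the *continuous* in-lung intensity distribution that FCM
  clusters into nested shells, as on real films;
* parabolic rib bands of limited contrast; clavicle bands near the apex whose
  contrast fades at the midline (as clavicle shadows vanish into the
  mediastinum), so their thresholded components stay confined to one lateral
  half, the configuration the clavicle rule targets;
* diaphragm domes with costophrenic angles; optional consolidation blob;
* additive Gaussian noise, default sd 2% of the dynamic range;
* mobile variants: 12% dark border with three bright text-like glyph blocks
  centered in the border ring; the inverted variant additionally flips the
  grayscale. Fixture sets are written as 16-bit PNG (optionally a minimal
  12-bit DICOM twin) with a YAML manifest; everything is bit-reproducible
  from the seed.

What the phantom does **not** emulate: true rib-cage curvature and posterior/
anterior rib crossings, scapulae, cardiac silhouette asymmetry, exposure
inhomogeneity, scatter, grid-line artifacts, pathology beyond one blob.
Passing phantom tests therefore demonstrates the pipeline's mechanics —
stage contracts, rule boundary behavior, cross-profile consistency,
determinism — not clinical-grade accuracy on hospital data; on real datasets
the published behavior of this method class (overlap in the 0.7–0.87 range
depending on machine) should be expected instead.

## Problem sizes and defaults

The default test and reproduction batch is 20 phantoms at 512×512 — large
enough for stable means (the six-measure summary moves by < 0.01 between
disjoint seed ranges) while a full batch completes in well under a minute.
FCM runs exactly as in production (65,536 pixels, 8 clusters).

## Known limitations

* The automatic threshold depends on the absolute response scale; inputs are
  normalized to a 12-bit-equivalent scale rather than using native units.
* The threshold histogram's peak structure is noise-driven on smooth
  gradients; the percentile fallback keeps the pipeline total, but
  orientations that fall back contribute slightly fatter outlines.
* Aspect ratio is not preserved at the fixed 512/256 working sizes; strongly
  non-square crops are distorted during processing (masks are mapped back
  through the same transform, so geometry is consistent).
* The c5 consolidation radius (6% of width) is calibrated to vessel/rib
  shadow spacing; images at very different effective magnification may need
  the config knob.
* A hook exists for a spine-axis estimation step, but no method is attached
  to it; the rules work on image-width fractions and do not require it.
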