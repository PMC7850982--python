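# Methods

This note documents the models, conventions, parameters, and design
choices behind `uvcollagen`, and what the phantom-based validation
does and does not establish.

## Imaging model and conventions

Images are `H × W × 3` float arrays in `[0, 1]`, row-major, 0-based,
origin top-left.  All physical outputs are in microns via a single
isotropic `pixel_size_um`; when file metadata (TIFF resolution tags)
lacks it, it must be supplied explicitly — there is no silent default,
because every micron-valued quantity depends on it.  Orientations are
measured against the image x-axis in degrees on (−90°, 90°], positive
counter-clockwise in y-up convention.

## Focus fusion

A z-stack (canonically seven slices at 6.3-μm steps, reflecting a
vertical stage with that step limit) is collapsed by per-pixel
sharpness selection.  Sharpness is the local variance of the Laplacian
of Rec. 709 luminance in a `window_px` window (default 9); an optional
Gaussian high-pass (`highpass_sigma_px`, default 10 in the pipeline)
feeds the *decision* only — fused pixel values always come from the
unfiltered slices, so fusion never invents values.  The argmax height
map is median-smoothed (5 × 5) to suppress speckled slice selection,
and ties go to the lowest slice index for determinism.  The z-step is
metadata: fusion is purely ordinal in z.

This local-sharpness criterion is this package's own documented
substitute for model-based extended-depth-of-field algorithms; it is
standard, testable, and dependency-free.

## HSV structural segmentation

After per-channel percentile histogram stretching (default percentiles
(1, 99); robust to hot pixels), pixels are classified by open-interval
HSV boxes calibrated for UV-excited pancreatic tumor surfaces:

| class    | hue                      | saturation       | value            |
|----------|--------------------------|------------------|------------------|
| nuclei   | 0.449 < h < 0.770        | 0 < s < 1        | 0.656 < v < 1    |
| collagen | h > 0.750 **or** h < 0.464 | 0 < s < 1      | 0.341 < v < 1    |
| vacuole  | h > 0.773 **or** h < 0.113 | 0.475 < s < 1  | 0 < v < 0.477    |

Anything matching no box is cytoplasm.  The nuclei and collagen hue
ranges mathematically overlap on h ∈ (0.449, 0.464) at v > 0.656; a
fixed priority nuclei → collagen → vacuole resolves the overlap
deterministically, so the classification is independent of pixel
visiting order.  Two consequences worth knowing:

- the collagen box wraps through red, so saturated warm pinks of
  moderate value legitimately classify as collagen — these boxes are
  tissue-specific and need recalibration for other stains/tissues;
- the bounds are strict, so a channel saturated to exactly 1.0 by
  stretching falls out of every box; pipeline configurations for
  full-range images should stretch with (0, 100).

Post-processing: every 8-connected nuclei/collagen/vacuole component
with strictly fewer than `min_region_px` = 200 pixels is reassigned to
cytoplasm (strict inequality: 199 goes, 200 stays).  Before fiber
analysis, non-collagen islands that are 4-connected, do not touch the
image border, and have at most `max_hole_px` (default 2000 ≈ one
nucleus at 0.5 μm/px) pixels are filled into the collagen mask —
surface nuclei resting on a strand would otherwise punch holes that
derail skeletonization.  The 8-connected/4-connected pairing is the
conventional complement choice that keeps fills conservative.

Necrosis (light yellow/orange surface regions) has no universal HSV
box; `classify_necrosis` requires explicit user cutoffs and stores the
mask for exclusion from ROI statistics.  The red channel is exposed
directly as a perfusion readout for Texas-Red-labeled dextran.

## Fiber-network decomposition

1. **Thickness map**: exact Euclidean distance transform of the
   collagen mask, with the image frame treated as background (an
   isolated pixel has distance 1).
2. **Thickness thresholding**: a connected component survives iff its
   maximal distance value reaches `thickness_threshold_um / (2 ·
   pixel_size_um)`.  This is component-wise, not pixel-wise: the
   intent is to remove whole objects that are everywhere thin —
   cross-sections of strands cut perpendicular to the surface and
   defocus-clumped debris — while pixel-wise erosion would shred
   legitimate strands.  No universal threshold exists; the default of
   4 μm suits the bundled phantoms and is a required choice for real
   data.
3. **Skeletonization** of the thresholded binary mask
   (topology-preserving thinning); distance values are read along the
   skeleton.  Skeletonizing the binary mask and sampling the distance
   map is the standard realization of "skeletonizing the thickness
   map".
4. **Branchpoints** are skeleton pixels with ≥ 3 skeleton neighbors
   (8-connectivity).  Branchpoints plus their skeleton 8-neighborhood
   (radius 1) are removed — single-pixel removal can fail to
   disconnect an X-crossing — and the remaining components become
   strands; chains shorter than `min_strand_px` = 5 are dropped as
   fragments.
5. **Measurement** per strand: length is the polyline arc length of
   the path-ordered chain (axial steps 1, diagonal √2) — a curved
   strand's length, not its bounding-box extent.  Thickness is twice
   the mean distance value over the chain.  Orientation is the
   best-fit-ellipse major-axis angle of the chain pixels.

**Known estimator bias.** Doubling the centerline distance
overestimates the true ribbon width by about +1 px: the distance from
a centerline pixel to the nearest *background pixel center* exceeds
the mask half-width by ~0.5 px on each side.  The 40 × 5 ribbon reads
6 px.  This is a property of the doubled-distance definition itself
and is left intact and tested rather than corrected.  Similarly, the
skeleton retracts by roughly one half-width at each strand end, so
measured lengths run a few percent short for slender fibers — and
substantially short for stubby ones, which is why recovery guarantees
are stated for fibers long relative to their thickness.

A strand belongs to an ROI iff its centerline centroid lies inside, so
any ROI partition counts each strand exactly once.  Branchpoint count
per area is available from the decomposition as a crosslinking
diagnostic but is not part of the summary schema.

## Virtual trichrome (color transfer)

Reinhard moment matching conditioned on the structural class, in
CIELAB (D65 white point, sRGB companding assumed — the camera profile
is not modeled).  For each of nuclei, collagen, and cytoplasm: chosen
channels are first inverted — L → 100 − L, a → −a, b → −b (inversion
about 0, a documented choice) — then each channel is mapped by
`v′ = (v − μ_in)(σ_ref/σ_in) + μ_ref` against a reference image's
same-class statistics; σ_in = 0 degenerates to a pure mean shift.
Flip-before-match makes the output class moments equal the reference's
exactly before gamut clipping, which turns the "distribution is
preserved" claim into an exact testable property: output histograms
are affine images of the (flipped) input histograms.  Default flips —
nuclei {L} (bright fluorescent nuclei become dark stained ones),
collagen {L, a, b} (both intensity and hue transition), cytoplasm {}.
Vacuoles are exempt and stay dark; classes missing from the reference
pass through with a warning.

## Mosaic stitching

Motorized-stage acquisition justifies a pure-translation model.  Tile
origins start from the nominal step `tile_size · (1 − overlap)` (10%
overlap by default); each tile's step against its chaining neighbor
(row-major: left neighbor, or the tile above for column 0) is refined
by maximizing the normalized cross-correlation of the overlap strips
over a ± `search_radius_px` window (default 5), falling back to
nominal on textureless strips.  Blending uses separable linear
feathering over the overlap width, so identical overlapping content
reconstructs exactly.  Stage-drift handling beyond pairwise chaining
and cross-modality registration to histology are out of scope.

## ROI statistics and group comparison

ROIs (default 50 of 600 × 400 μm) are placed by uniform rejection
sampling, fully inside the image and off the exclusion mask, with a
bounded budget and a diagnostic on infeasibility; the sampler is
seeded and supports per-tumor or pooled sampling by configuration.
Welch's two-sample t-test (two-tailed, unequal variances):

    t = (x̄_a − x̄_b) / √(s²_a/n_a + s²_b/n_b),

with Welch–Satterthwaite degrees of freedom, is applied per metric
(collagen content %, thickness, length, orientation) at α = 0.05, with
no multiple-testing correction across the four metrics — each metric
is reported at its own per-test level, deliberately.  Percent change
is relative to the control mean, so a positive value reads as a
reduction under treatment.  Mouse-level clustering of ROIs is not
modeled.

## Synthetic phantoms: what they emulate, and what they do not

The generator draws curvilinear collagen ribbons (quadratic Bézier
centerlines with bowing bounded to ≈ 6% of length, so arc ≈ chord
within ~2%), with per-fiber length/thickness/orientation drawn from
configurable normal laws; purple nucleus ellipses, a fraction
deliberately centered on strands to exercise hole filling; dark
vacuole disks; flat class colors plus Gaussian sensor noise; and
defocus stacks whose per-pixel Gaussian blur grows with distance from
a tilted surface plane.  Truth is rendered before noise: a full label
map, the exact collagen fraction, and per-fiber truth in which length
is the *continuous* centerline arc length (summing steps between
rounded pixels would inflate the arc by staircase detours) and
orientation is the best-fit line to the centerline pixels — the same
estimator the measurement stage uses, so oracle comparisons are
unambiguous.

Defaults model dense PDAC stroma at 0.5 μm/px (a 10× objective filling
an APS-C sensor): 768² px, 40 fibers of 60 ± 25 μm length and
8 ± 2.5 μm thickness, chaotic orientations (sd 50°), crossing
probability 0.3, 60 nuclei of 12 × 8 μm, 8 vacuoles of 10 μm radius,
noise sd 0.02.  At this scale a nucleus (~300 px) correctly survives
the 200-px rule.  Palette colors are validated at construction to sit
inside their HSV boxes (and the cytoplasm color outside all of them)
with margins of several noise standard deviations; the cytoplasm
default is a muted gray rather than a true pink because the wrapped
collagen hue box claims saturated warm pinks.

Phantoms are *not* photorealistic: no tissue texture, no wavelength-
dependent optics, flat class colors, additive Gaussian noise, and
exactly ribbon-shaped fibers.  Passing recovery tests therefore shows
that the algorithmic chain is correct and well-calibrated on geometry
it can represent; it does not certify segmentation accuracy on real
tissue, where staining variability, autofluorescence, and surface
irregularity dominate.

## Validation conditions and problem sizes

The test suite validates: exact agreement of the distance transform
with an independent nearest-background computation on 200 random masks
up to 64²; hand-enumerated HSV truth tables and the 199/200 boundary;
fiber recovery on fixed-seed non-crossing phantoms of 22 slender
fibers (640², 1 μm/px; count within 10%, orientation within 5°, length
within 10%, thickness overestimate within 2 px + 10%); fusion gain on
7-slice 6.3-μm stacks; color-transfer moment error below 1e-6
pre-clip; exact mosaic reconstruction with ±3 px jitter; Welch
agreement with the closed form to 1e-10, null rejection in
[0.04, 0.06] over 2000 replicates at group sizes 23/19, and detection
of a constructed 13% collagen reduction (treated fiber count 26 vs 30
across 23/19 patches of 360²).  `scripts/acceptance.py` recomputes all
of these from scratch at the same problem sizes, chosen so the whole
suite runs in well under a minute on one CPU.
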