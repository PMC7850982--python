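# uvcollagen

Collagen morphometry for microscopy with UV surface excitation (MUSE)
of fresh tumor tissue.

Pancreatic adenocarcinoma is dominated by desmoplasia — a dense
collagenous stroma that drives stiffness, drug resistance, and poor
perfusion.  Deep-UV (sub-300 nm) illumination excites only a thin
surface layer of bulk tissue, so a stained fresh specimen yields
optical-section-like RGB images without fixation or sectioning:
collagen fluoresces yellow-green, nuclei purple, and vacuoles appear
as dark holes.  `uvcollagen` turns such images into quantitative
stromal readouts for researchers assessing therapies (e.g.
photodynamic priming) that aim to modulate collagen.

## What it does

- **Focus fusion** — collapse a z-stack (e.g. seven slices at 6.3-μm
  steps) into one all-in-focus image by per-pixel sharpness selection
  (local variance of the Laplacian of luminance), with a height map as
  a by-product.
- **HSV structural segmentation** — classify every pixel as nuclei /
  collagen / vacuole / cytoplasm by hue–saturation–value boxes
  calibrated for UV-excited pancreatic tumor surfaces, with a strict
  `< 200 px` small-region rule and hole filling of the collagen mask.
- **Fiber-network decomposition** — Euclidean distance transform
  (thickness map) `D(x) = min_{y ∉ M} ‖x − y‖`, component-wise
  thickness thresholding, skeletonization, branchpoint splitting, and
  per-strand measurement:
  - length: arc length of the centerline polyline (diagonal steps
    count √2),
  - thickness: `2 · mean(D)` over the centerline,
  - orientation: best-fit-ellipse major-axis angle in (−90°, 90°].
- **Virtual trichrome** — structure-conditional Reinhard color
  transfer in CIELAB, `v′ = (v − μ_in)(σ_ref/σ_in) + μ_ref`, with
  per-class channel inversions (nuclei: L; collagen: L, a, b), mapping
  the UV palette to Masson's-trichrome colors while preserving each
  class's color distribution.
- **Mosaic stitching** — translation-only registration of tile grids
  acquired with ~10% overlap (normalized cross-correlation of overlap
  strips) and feathered blending.
- **ROI statistics** — random sampling of regions of interest (default
  50 ROIs of 0.6 × 0.4 mm, necrosis excluded) and per-metric group
  comparison with Welch's t-test (two-tailed, unequal variances,
  Welch–Satterthwaite df, α = 0.05), reporting percent change relative
  to control.
- **Synthetic phantoms** — a generator of tumor-surface phantoms with
  exhaustive ground truth (label maps, per-fiber parameters, collagen
  fraction, defocus stacks, trichrome references) against which every
  stage is validated.

## Worked example

```sh
python examples/03_segment_and_measure_fibers.py
```

```
pixel counts: {'CYTOPLASM': 205027, 'NUCLEI': 16834, 'COLLAGEN': 30312, 'VACUOLE': 9971}
collagen content: 11.6% (truth 11.7%)
strands: 83 (the 20 generated fibers split at crossings)
mean length      13.0 +/- 13.7 um
mean thickness    5.4 +/- 2.8 um
mean angle        0.2 +/- 50.2 deg
```

The phantom's true collagen fraction is 11.7%; segmenting the rendered
image by the HSV rules recovers 11.6%.  The 20 generated fibers yield
83 strands because the decomposition deliberately cuts the network at
every crossing — a strand is a branch-free centerline segment.  Group
comparison works the same way (`examples/06_group_comparison.py`): a
treated group constructed with 26/30 of the control fiber count is
reported as a 12.2% collagen reduction, significant by Welch's test at
group sizes 23 vs 19.

Other examples cover phantom generation (`01`), focus fusion (`02`),
virtual trichrome recoloring (`04`), and tile stitching (`05`).  A thin
CLI mirrors the stages (`uvcollagen fixtures|fuse|segment|fibers|
recolor|stitch|compare|run`).

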