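"""Generate a synthetic tumor-surface phantom and inspect its ground truth.

The phantom emulates a UV-excited fresh-tissue image: yellow-green
collagen ribbons, purple nuclei (some sitting on top of strands), dark
vacuoles, and a muted gray cytoplasm background.  Every structure is
recorded in a truth label map and a truth fiber table, which is what
makes the downstream stages testable.
"""

import uvcollagen as uv

spec = uv.PhantomSpec(image_size_px=(512, 512), n_fibers=20, rng_seed=42)
image, truth = uv.generate_phantom(spec)

print(f"image: {image.shape[0]} x {image.shape[1]} px at {image.pixel_size_um} um/px")
print(f"true collagen fraction: {truth.collagen_fraction:.4f}")
print(f"true fibers: {len(truth.fiber_truth)}")
print(truth.fiber_truth[["strand_id", "length_um", "thickness_um", "orientation_deg"]]
      .describe().loc[["mean", "std"]].round(2))
# The mean/std rows summarize the drawn fiber population: lengths and
# thicknesses in microns, orientations in degrees against the x-axis.
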