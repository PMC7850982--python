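"""Fuse a defocus z-stack into one all-in-focus image.

Stiff tumor tissue has an irregular surface, so a single focal plane
leaves part of the field blurred.  We simulate a 7-slice stack at
6.3-um steps over a tilted surface, fuse it by per-pixel sharpness
selection, and show that the fusion correlates with the sharp phantom
better than any single slice does.
"""

import numpy as np

import uvcollagen as uv

spec = uv.PhantomSpec(image_size_px=(256, 256), n_fibers=8, n_nuclei=12, rng_seed=7)
sharp, _ = uv.generate_phantom(spec)
stack = uv.generate_defocus_stack(
    sharp, n_slices=7, z_step_um=6.3, blur_per_um=0.3,
    surface=uv.SurfacePlane(z0_um=0.0, gx_um_per_px=0.22),
)
result = uv.fuse_stack(stack)


def corr(a, b):
    a, b = a.ravel() - a.mean(), b.ravel() - b.mean()
    return float(a @ b / np.sqrt((a @ a) * (b @ b)))


for i, s in enumerate(stack.slices):
    print(f"slice {i}: correlation with sharp phantom = {corr(s.pixels, sharp.pixels):.4f}")
print(f"fused  : correlation with sharp phantom = {corr(result.fused.pixels, sharp.pixels):.4f}")
print(f"height map spans slices {result.height_map.min()}..{result.height_map.max()}")
# The fused correlation exceeds every single-slice correlation; the
# height map records which slice was sharpest at each pixel and climbs
# across the field following the surface tilt.
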