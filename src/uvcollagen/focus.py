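"""Focus fusion (depth-of-field correction) for surface-microscopy z-stacks.

Stiff tumor tissue presents an irregular surface, so any single focal
plane leaves much of the field defocused; a short z-stack captures each
region in focus somewhere.  Fusion selects, per pixel, the slice with
maximal local sharpness and copies its value — no pixel is invented.

Sharpness is the local variance of the Laplacian of the luminance
channel (Rec. 709 weights) in a small window; an optional Gaussian
high-pass can be applied to the slices before the sharpness decision
(the fused pixels always come from the unfiltered slices).  The raw
per-pixel argmax tends to speckle near ties, so the height map is
median-smoothed (5x5) by default before pixels are gathered.  Ties in
the argmax go to the lowest slice index, which makes fusion
deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage

from .core import RGBImage, ZStack

__all__ = ["FocusResult", "highpass_filter", "sharpness_map", "fuse_stack"]

# Rec. 709 luma weights
_LUMA = np.array([0.2126, 0.7152, 0.0722])


@dataclass
class FocusResult:
    """Fused all-in-focus image plus the per-pixel selected slice index."""

    fused: RGBImage
    height_map: np.ndarray

    def __post_init__(self) -> None:
        self.height_map = np.asarray(self.height_map)
        if self.height_map.shape != self.fused.shape:
            raise ValueError("height_map shape must match fused image shape")


def highpass_filter(image: RGBImage, sigma_px: float) -> RGBImage:
    """Gaussian high-pass, rescaled per channel to [0, 1] by min-max.

    The output is ``input - Gaussian(input, sigma)`` mapped affinely to
    the unit interval channel by channel.  A channel with no residual
    contrast maps to zero.  For large sigma the Gaussian approaches the
    channel mean on a bounded image, so the result approaches the
    mean-subtracted input (after rescale).
    """
    if sigma_px <= 0:
        raise ValueError(f"sigma_px must be positive, got {sigma_px}")
    out = np.empty_like(image.pixels)
    for c in range(3):
        low = ndimage.gaussian_filter(image.pixels[..., c], sigma=sigma_px, mode="nearest")
        resid = image.pixels[..., c] - low
        lo, hi = float(resid.min()), float(resid.max())
        if hi > lo:
            out[..., c] = (resid - lo) / (hi - lo)
        else:
            out[..., c] = 0.0
    return RGBImage(out, image.pixel_size_um)


def _luminance(image: RGBImage) -> np.ndarray:
    return image.pixels @ _LUMA


def sharpness_map(image: RGBImage, window_px: int = 9) -> np.ndarray:
    """Local variance of the Laplacian of luminance; non-negative.

    ``window_px`` must be odd and at least 3.  Uniform images map to
    zero everywhere; scaling intensities by a factor scales the map by
    its square (variance is quadratic in intensity).
    """
    if window_px < 3 or window_px % 2 == 0:
        raise ValueError(f"window_px must be odd and >= 3, got {window_px}")
    lap = ndimage.laplace(_luminance(image), mode="nearest")
    mean = ndimage.uniform_filter(lap, size=window_px, mode="nearest")
    mean_sq = ndimage.uniform_filter(lap * lap, size=window_px, mode="nearest")
    return np.maximum(mean_sq - mean * mean, 0.0)


def fuse_stack(
    stack: ZStack,
    window_px: int = 9,
    smooth_height: bool = True,
    highpass_sigma_px: Optional[float] = None,
) -> FocusResult:
    """Fuse a z-stack into one all-in-focus image.

    Each output pixel is copied from the slice with maximal local
    sharpness at that pixel; ties go to the lowest slice index.  When
    ``highpass_sigma_px`` is given, the sharpness decision is made on
    high-pass-filtered slices (fused pixels still come from the
    original slices).  A single-slice stack returns that slice with a
    zero height map.
    """
    n = len(stack)
    if n == 1:
        return FocusResult(stack.slices[0].copy(), np.zeros(stack.shape, dtype=np.intp))
    decision_slices = stack.slices
    if highpass_sigma_px is not None:
        decision_slices = [highpass_filter(s, highpass_sigma_px) for s in stack.slices]
    sharp = np.stack([sharpness_map(s, window_px) for s in decision_slices], axis=0)
    height = np.argmax(sharp, axis=0)  # ties resolve to the lowest index
    if smooth_height:
        height = ndimage.median_filter(height, size=5, mode="nearest")
    pixels = np.stack([s.pixels for s in stack.slices], axis=0)
    rows, cols = np.indices(stack.shape)
    fused = pixels[height, rows, cols, :]
    return FocusResult(
        RGBImage(fused, stack.slices[0].pixel_size_um), height.astype(np.intp)
    )
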