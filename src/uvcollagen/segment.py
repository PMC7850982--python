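"""HSV structural segmentation of UV-fluorescence tumor-surface images.

The classifier assigns every pixel to one of four structural classes —
nuclei, collagen, vacuole, cytoplasm — from hue/saturation/value boxes
calibrated for UV-excited pancreatic tumor surfaces (purple nuclei,
yellow-green collagen, dark round vacuoles; anything else is
cytoplasm).  The printed nuclei and collagen hue ranges overlap on
``h in (0.449, 0.464)`` at high value; classification therefore applies
a fixed priority nuclei > collagen > vacuole so the result is
deterministic and independent of pixel visiting order.

Post-processing follows the same region-size logic used at the design
magnification: any nuclei/collagen/vacuole component of fewer than 200
pixels is considered cytoplasm, and nucleus-sized islands enclosed by
collagen are filled back into the collagen mask before fiber analysis
(surface nuclei sitting on top of a strand would otherwise punch holes
that derail skeletonization).
"""

from __future__ import annotations

import logging
from typing import Optional

import numpy as np
from scipy import ndimage
from skimage.color import rgb2hsv
from skimage.measure import label as cc_label

from .core import ClassCutoff, HsvCutoffs, RGBImage, StructureLabel, StructureLabelMap

__all__ = [
    "stretch_histogram",
    "classify_hsv",
    "reassign_small_regions",
    "fill_collagen_holes",
    "extract_red_channel",
    "classify_necrosis",
]

logger = logging.getLogger(__name__)

_FOREGROUND = (StructureLabel.NUCLEI, StructureLabel.COLLAGEN, StructureLabel.VACUOLE)


def stretch_histogram(image: RGBImage, p_low: float = 1.0, p_high: float = 99.0) -> RGBImage:
    """Per-channel percentile histogram stretch, clipped to [0, 1].

    The ``p_low`` percentile maps to 0 and ``p_high`` to 1 in each
    channel independently.  A constant channel (zero percentile range)
    is returned unchanged with a logged warning.
    """
    if not (0 <= p_low < p_high <= 100):
        raise ValueError(f"percentiles must satisfy 0 <= p_low < p_high <= 100, got ({p_low}, {p_high})")
    out = image.pixels.copy()
    for c in range(3):
        lo, hi = np.percentile(image.pixels[..., c], [p_low, p_high])
        if hi <= lo:
            logger.warning("channel %d has zero percentile range; left unchanged", c)
            continue
        out[..., c] = np.clip((image.pixels[..., c] - lo) / (hi - lo), 0.0, 1.0)
    return RGBImage(out, image.pixel_size_um)


def classify_hsv(image: RGBImage, cutoffs: Optional[HsvCutoffs] = None) -> StructureLabelMap:
    """Classify every pixel by HSV box rules.

    Rules are evaluated with fixed priority nuclei > collagen >
    vacuole; pixels matching no box are cytoplasm.  The function is
    total: the output is always a full partition.
    """
    cutoffs = cutoffs or HsvCutoffs()
    hsv = rgb2hsv(image.pixels)
    h, s, v = hsv[..., 0], hsv[..., 1], hsv[..., 2]
    labels = np.full(image.shape, int(StructureLabel.CYTOPLASM), dtype=np.uint8)
    unassigned = np.ones(image.shape, dtype=bool)
    for lab, box in (
        (StructureLabel.NUCLEI, cutoffs.nuclei),
        (StructureLabel.COLLAGEN, cutoffs.collagen),
        (StructureLabel.VACUOLE, cutoffs.vacuole),
    ):
        hit = box.contains(h, s, v) & unassigned
        labels[hit] = int(lab)
        unassigned &= ~hit
    return StructureLabelMap(labels)


def reassign_small_regions(label_map: StructureLabelMap, min_region_px: int = 200) -> StructureLabelMap:
    """Relabel small foreground components as cytoplasm.

    Every 8-connected component of nuclei, collagen, or vacuole with
    strictly fewer than ``min_region_px`` pixels becomes cytoplasm;
    components at or above the bound are untouched.  Idempotent.
    """
    if min_region_px < 0:
        raise ValueError("min_region_px must be non-negative")
    labels = label_map.labels.copy()
    if min_region_px > 0:
        for lab in _FOREGROUND:
            mask = labels == int(lab)
            if not mask.any():
                continue
            comps, n = cc_label(mask, connectivity=2, return_num=True)
            if n == 0:
                continue
            sizes = np.bincount(comps.ravel())
            small = sizes < min_region_px
            small[0] = False
            labels[small[comps]] = int(StructureLabel.CYTOPLASM)
    return StructureLabelMap(labels, label_map.necrosis_mask)


def fill_collagen_holes(label_map: StructureLabelMap, max_hole_px: int = 2000) -> StructureLabelMap:
    """Fill enclosed non-collagen islands back into the collagen mask.

    A hole is a 4-connected component of non-collagen pixels that does
    not touch the image border (hence is fully enclosed by collagen in
    the binary collagen/background view) and has at most
    ``max_hole_px`` pixels.  Border-touching regions are never filled;
    ``max_hole_px = 0`` is a no-op.
    """
    if max_hole_px < 0:
        raise ValueError("max_hole_px must be non-negative")
    labels = label_map.labels.copy()
    if max_hole_px > 0:
        background = labels != int(StructureLabel.COLLAGEN)
        comps, n = cc_label(background, connectivity=1, return_num=True)
        if n > 0:
            border_ids = np.unique(
                np.concatenate([comps[0, :], comps[-1, :], comps[:, 0], comps[:, -1]])
            )
            sizes = np.bincount(comps.ravel())
            fill = (sizes <= max_hole_px) & (sizes > 0)
            fill[0] = False
            fill[border_ids] = False
            labels[fill[comps]] = int(StructureLabel.COLLAGEN)
    return StructureLabelMap(labels, label_map.necrosis_mask)


def extract_red_channel(image: RGBImage) -> np.ndarray:
    """Red channel as a perfusion-intensity map in [0, 1].

    UV-excited Texas Red dextran emits into the red channel of the RGB
    camera, so channel 0 serves as a direct perfusion readout.
    """
    return image.pixels[..., 0].copy()


def classify_necrosis(image: RGBImage, cutoffs: ClassCutoff) -> np.ndarray:
    """Boolean necrosis mask from a user-supplied HSV box.

    Light yellow/orange surface regions align with necrosis, but no
    universal box exists; explicit cutoffs are therefore required and
    no default is shipped.  The mask is meant to be stored on the label
    map so necrotic pixels are excluded from ROI statistics.
    """
    if cutoffs is None:
        raise ValueError("necrosis classification requires explicit HSV cutoffs")
    hsv = rgb2hsv(image.pixels)
    return cutoffs.contains(hsv[..., 0], hsv[..., 1], hsv[..., 2])
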