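"""Structure-conditional Reinhard color transfer to a trichrome palette.

UV-excited fluorescence renders collagen yellow-green on a dark field;
pathologists read Masson's trichrome, where collagen is blue, nuclei
are dark purple, and cytoplasm light pink.  The remapping works in
CIELAB (D65, sRGB companding): for each structural class separately,
selected channels are first inverted (L -> 100 - L; a, b -> -a, -b,
i.e. inversion about 0) and the per-channel mean/sd are then matched
to a reference image's same-class statistics.  Because the flip
precedes moment matching, the output class moments equal the
reference's exactly (before gamut clipping), and each class's channel
histograms are affine images of the input's — the color *distribution*
is preserved, only relocated.

Default flip policy: nuclei invert L (bright fluorescent nuclei become
dark, as stained nuclei are); collagen inverts all three channels
(intensity and hue both transition); cytoplasm is matched without
flips.  Vacuoles are exempt and stay dark.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
from skimage.color import lab2rgb, rgb2lab

from .core import RGBImage, StructureLabel, StructureLabelMap

__all__ = [
    "ColorStats",
    "ChannelFlipPolicy",
    "rgb_to_lab",
    "lab_to_rgb",
    "structure_stats",
    "remap_structure",
    "virtual_trichrome",
]

logger = logging.getLogger(__name__)

_CHANNELS = ("L", "a", "b")
_REMAPPED = (StructureLabel.NUCLEI, StructureLabel.COLLAGEN, StructureLabel.CYTOPLASM)


def rgb_to_lab(image: RGBImage) -> np.ndarray:
    """CIELAB (D65, sRGB companding) representation of the image."""
    return rgb2lab(image.pixels)


def lab_to_rgb(lab: np.ndarray, pixel_size_um: float) -> RGBImage:
    """Back to RGB; out-of-gamut values are clipped into [0, 1]."""
    return RGBImage(np.clip(lab2rgb(lab), 0.0, 1.0), pixel_size_um)


@dataclass
class ColorStats:
    """Per-class, per-channel Lab means and standard deviations.

    ``stats[class][channel] = (mean, sd)``; classes absent from the
    label map (or with fewer than two pixels, where an sd is
    meaningless) have no entry.
    """

    stats: dict[StructureLabel, dict[str, tuple[float, float]]]

    def has(self, label: StructureLabel) -> bool:
        return label in self.stats

    def get(self, label: StructureLabel, channel: str) -> tuple[float, float]:
        return self.stats[label][channel]


@dataclass(frozen=True)
class ChannelFlipPolicy:
    """Which Lab channels to invert, per class, before moment matching."""

    nuclei: frozenset[str] = frozenset({"L"})
    collagen: frozenset[str] = frozenset({"L", "a", "b"})
    cytoplasm: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        for name in ("nuclei", "collagen", "cytoplasm"):
            flips = getattr(self, name)
            if not set(flips) <= set(_CHANNELS):
                raise ValueError(f"flip channels for {name} must be a subset of {_CHANNELS}")

    def for_label(self, label: StructureLabel) -> frozenset[str]:
        return {
            StructureLabel.NUCLEI: self.nuclei,
            StructureLabel.COLLAGEN: self.collagen,
            StructureLabel.CYTOPLASM: self.cytoplasm,
        }.get(label, frozenset())


def structure_stats(lab: np.ndarray, labels: StructureLabelMap) -> ColorStats:
    """Per-class Lab channel moments over that class's pixels only."""
    if lab.shape[:2] != labels.shape:
        raise ValueError("lab image and label map shapes differ")
    out: dict[StructureLabel, dict[str, tuple[float, float]]] = {}
    for label in _REMAPPED:
        mask = labels.mask(label)
        n = int(mask.sum())
        if n < 2:
            if n == 1:
                logger.warning("class %s has a single pixel; stats omitted", label.name)
            continue
        values = lab[mask]
        out[label] = {
            ch: (float(values[:, i].mean()), float(values[:, i].std()))
            for i, ch in enumerate(_CHANNELS)
        }
    return ColorStats(out)


def _flip_channel(values: np.ndarray, channel: str) -> np.ndarray:
    return 100.0 - values if channel == "L" else -values


def remap_structure(
    lab: np.ndarray,
    mask: np.ndarray,
    input_stats: Mapping[str, tuple[float, float]],
    reference_stats: Mapping[str, tuple[float, float]],
    flips: frozenset[str] = frozenset(),
) -> np.ndarray:
    """Flip-then-moment-match one class's pixels; returns a new Lab image.

    For each channel, flipped values v are mapped to
    ``(v - mu_in) * (sigma_ref / sigma_in) + mu_ref``; a zero input sd
    degenerates to a pure mean shift.  ``input_stats`` must describe
    the *flipped* input distribution when the channel is flipped — use
    the moments this function's callers compute after flipping, or
    note that flipping only negates/reflects the moments:
    mu -> 100 - mu (L) or -mu (a, b), sigma unchanged.  For
    convenience this function accepts raw (unflipped) input stats and
    performs that reflection itself.
    """
    out = lab.copy()
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return out
    for i, ch in enumerate(_CHANNELS):
        mu_in, sd_in = input_stats[ch]
        mu_ref, sd_ref = reference_stats[ch]
        values = lab[..., i][mask]
        if ch in flips:
            values = _flip_channel(values, ch)
            mu_in = float(_flip_channel(np.array(mu_in), ch))
        scale = (sd_ref / sd_in) if sd_in > 0 else 0.0
        out[..., i][mask] = (values - mu_in) * scale + mu_ref
    return out


def virtual_trichrome(
    image: RGBImage,
    labels: StructureLabelMap,
    reference: RGBImage,
    reference_labels: StructureLabelMap,
    flips: Optional[ChannelFlipPolicy] = None,
) -> RGBImage:
    """Remap a UV-fluorescence image to the reference's trichrome palette.

    Full pipeline: RGB -> Lab, per-class flip + moment matching against
    the reference's same-class statistics, Lab -> RGB (gamut-clipped).
    Vacuole and any pixels of classes missing from the reference pass
    through unchanged (with a warning for the latter).
    """
    if image.shape != labels.shape:
        raise ValueError("image and label map shapes differ")
    flips = flips or ChannelFlipPolicy()
    lab = rgb_to_lab(image)
    in_stats = structure_stats(lab, labels)
    ref_stats = structure_stats(rgb_to_lab(reference), reference_labels)
    for label in _REMAPPED:
        if not in_stats.has(label):
            continue
        if not ref_stats.has(label):
            logger.warning(
                "class %s present in input but absent in reference; left unchanged", label.name
            )
            continue
        lab = remap_structure(
            lab,
            labels.mask(label),
            in_stats.stats[label],
            ref_stats.stats[label],
            flips.for_label(label),
        )
    return lab_to_rgb(lab, image.pixel_size_um)
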