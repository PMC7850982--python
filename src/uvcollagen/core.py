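"""Shared domain types for the UV-fluorescence stromal-imaging pipeline.

Conventions used throughout the package:

* pixel coordinates are 0-based, row-major ``(row, col)``, origin top-left;
* image intensities are floats in ``[0, 1]``, shape ``H x W x 3``;
* physical scale enters only through ``pixel_size_um`` (isotropic microns
  per pixel) — it must be supplied explicitly when absent from file
  metadata, because every micron-valued output depends on it;
* fiber orientation is measured against the image x-axis (columns), in
  degrees, on the half-open interval ``(-90, 90]``, with positive angles
  rotating counter-clockwise in conventional (y-up) orientation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "StructureLabel",
    "RGBImage",
    "ZStack",
    "StructureLabelMap",
    "FiberRecord",
    "FIBER_COLUMNS",
    "make_fiber_table",
    "empty_fiber_table",
    "ClassCutoff",
    "HsvCutoffs",
    "AnalysisConfig",
]


class StructureLabel(IntEnum):
    """Per-pixel structural class of the tumor surface image."""

    CYTOPLASM = 0
    NUCLEI = 1
    COLLAGEN = 2
    VACUOLE = 3


@dataclass
class RGBImage:
    """An RGB microscopy image with a physical pixel size.

    Parameters
    ----------
    pixels
        ``H x W x 3`` float array with all channel values in ``[0, 1]``.
    pixel_size_um
        Isotropic sampling pitch in microns per pixel; must be finite
        and positive.
    """

    pixels: np.ndarray
    pixel_size_um: float

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError(f"expected H x W x 3 pixels, got shape {self.pixels.shape}")
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise ValueError("image must contain at least one pixel")
        if not np.isfinite(self.pixels).all():
            raise ValueError("image contains non-finite values")
        lo, hi = float(self.pixels.min()), float(self.pixels.max())
        if lo < 0.0 or hi > 1.0:
            raise ValueError(f"channel values must lie in [0, 1]; range is [{lo}, {hi}]")
        self.pixel_size_um = float(self.pixel_size_um)
        if not np.isfinite(self.pixel_size_um) or self.pixel_size_um <= 0:
            raise ValueError(f"pixel_size_um must be finite and positive, got {self.pixel_size_um}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[0], self.pixels.shape[1]

    def copy(self) -> "RGBImage":
        return RGBImage(self.pixels.copy(), self.pixel_size_um)


@dataclass
class ZStack:
    """An ordered z-stack of same-shape RGB slices.

    The default step mirrors the acquisition geometry this pipeline was
    designed around: stacks of seven slices taken at 6.3-um vertical
    increments.  Fusion itself is purely ordinal in z; the step is
    metadata.
    """

    slices: list[RGBImage]
    z_step_um: float = 6.3

    def __post_init__(self) -> None:
        if len(self.slices) < 1:
            raise ValueError("a z-stack needs at least one slice")
        shape0 = self.slices[0].shape
        for i, s in enumerate(self.slices):
            if s.shape != shape0:
                raise ValueError(f"slice {i} shape {s.shape} differs from slice 0 shape {shape0}")
        self.z_step_um = float(self.z_step_um)
        if not np.isfinite(self.z_step_um) or self.z_step_um <= 0:
            raise ValueError("z_step_um must be finite and positive")

    def __len__(self) -> int:
        return len(self.slices)

    @property
    def shape(self) -> tuple[int, int]:
        return self.slices[0].shape


@dataclass
class StructureLabelMap:
    """A per-pixel partition into the four structural classes.

    Every pixel carries exactly one label from :class:`StructureLabel`;
    this partition invariant is validated on construction.  An optional
    boolean ``necrosis_mask`` of the same shape flags pixels to exclude
    from downstream region statistics.
    """

    labels: np.ndarray
    necrosis_mask: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError(f"labels must be 2-D, got shape {self.labels.shape}")
        valid = {int(v) for v in StructureLabel}
        present = set(np.unique(self.labels).tolist())
        if not present.issubset(valid):
            raise ValueError(f"labels contain values outside {sorted(valid)}: {sorted(present - valid)}")
        self.labels = self.labels.astype(np.uint8)
        if self.necrosis_mask is not None:
            self.necrosis_mask = np.asarray(self.necrosis_mask, dtype=bool)
            if self.necrosis_mask.shape != self.labels.shape:
                raise ValueError("necrosis_mask shape must match labels shape")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def mask(self, label: StructureLabel) -> np.ndarray:
        """Boolean mask of one structural class."""
        return self.labels == int(label)

    def class_counts(self) -> dict[str, int]:
        return {lab.name: int(np.count_nonzero(self.labels == int(lab))) for lab in StructureLabel}

    def copy(self) -> "StructureLabelMap":
        return StructureLabelMap(
            self.labels.copy(),
            None if self.necrosis_mask is None else self.necrosis_mask.copy(),
        )


FIBER_COLUMNS = ["strand_id", "length_um", "thickness_um", "orientation_deg", "n_pixels"]


@dataclass(frozen=True)
class FiberRecord:
    """Morphometric measurements of one collagen strand."""

    strand_id: int
    length_um: float
    thickness_um: float
    orientation_deg: float
    n_pixels: int
    centroid_row: float = float("nan")
    centroid_col: float = float("nan")


def make_fiber_table(records: Sequence[FiberRecord]) -> pd.DataFrame:
    """Build a fiber table (one row per strand) from records.

    The canonical exchange columns are :data:`FIBER_COLUMNS`; centroid
    columns are carried in memory for ROI attribution but are not part
    of the CSV exchange schema.
    """
    if not records:
        return empty_fiber_table()
    df = pd.DataFrame([r.__dict__ for r in records])
    if df["strand_id"].duplicated().any():
        raise ValueError("strand_ids must be unique")
    return df

def empty_fiber_table() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "strand_id": pd.Series(dtype=np.int64),
            "length_um": pd.Series(dtype=np.float64),
            "thickness_um": pd.Series(dtype=np.float64),
            "orientation_deg": pd.Series(dtype=np.float64),
            "n_pixels": pd.Series(dtype=np.int64),
            "centroid_row": pd.Series(dtype=np.float64),
            "centroid_col": pd.Series(dtype=np.float64),
        }
    )


@dataclass(frozen=True)
class ClassCutoff:
    """An HSV box for one structural class, with strict (open) bounds.

    Hue is circular: when ``h[0] > h[1]`` the rule reads
    ``h > h[0] or h < h[1]`` (a wrap-around interval through red).
    """

    h: tuple[float, float]
    s: tuple[float, float]
    v: tuple[float, float]

    def __post_init__(self) -> None:
        for name in ("h", "s", "v"):
            lo, hi = getattr(self, name)
            if not (0.0 <= lo <= 1.0 and 0.0 <= hi <= 1.0):
                raise ValueError(f"{name} bounds must lie in [0, 1], got ({lo}, {hi})")

    def contains(self, h: np.ndarray, s: np.ndarray, v: np.ndarray) -> np.ndarray:
        h = np.asarray(h)
        s = np.asarray(s)
        v = np.asarray(v)
        h_lo, h_hi = self.h
        if h_lo <= h_hi:
            in_h = (h > h_lo) & (h < h_hi)
        else:  # circular interval through h = 0
            in_h = (h > h_lo) | (h < h_hi)
        return in_h & (s > self.s[0]) & (s < self.s[1]) & (v > self.v[0]) & (v < self.v[1])


@dataclass(frozen=True)
class HsvCutoffs:
    """HSV classification boxes for nuclei, collagen, and vacuoles.

    Defaults are the cutoffs calibrated for UV-excited fluorescence of
    pancreatic (PDAC) tumor surfaces: purple nuclei, yellow-green
    collagen, and dark round vacuoles.  Pixels matching none of the
    boxes are cytoplasm.  Other tissues need recalibrated boxes.
    """

    nuclei: ClassCutoff = field(
        default_factory=lambda: ClassCutoff(h=(0.449, 0.770), s=(0.0, 1.0), v=(0.656, 1.0))
    )
    collagen: ClassCutoff = field(
        default_factory=lambda: ClassCutoff(h=(0.750, 0.464), s=(0.0, 1.0), v=(0.341, 1.0))
    )
    vacuole: ClassCutoff = field(
        default_factory=lambda: ClassCutoff(h=(0.773, 0.113), s=(0.475, 1.0), v=(0.0, 0.477))
    )


@dataclass
class AnalysisConfig:
    """Run configuration for the whole pipeline.

    Parameters
    ----------
    hsv_cutoffs
        Structural classification boxes (see :class:`HsvCutoffs`).
    min_region_px
        Segmented regions with strictly fewer pixels than this are
        reassigned to cytoplasm (default 200: smaller than any nucleus,
        fiber, or vacuole at the design magnification).
    thickness_threshold_um
        Collagen components whose thickness map never reaches half this
        value are discarded before skeletonization; removes fiber
        cross-sections and defocus-clumped debris.  No universal value
        exists; the default of 4 um suits the bundled phantoms.
    max_hole_px
        Largest enclosed non-collagen island filled into the collagen
        mask before fiber analysis (nucleus-sized by default).
    min_strand_px
        Skeleton chains shorter than this are dropped after branchpoint
        splitting.
    roi_size_um, n_rois
        Region-of-interest sampling scheme for summary statistics
        (defaults: 50 ROIs of 600 x 400 um).
    alpha
        Two-tailed significance level for group comparisons.
    stretch_percentiles
        Per-channel percentiles mapped to 0 and 1 during histogram
        stretching.
    pixel_size_um
        Microns per pixel; required whenever image metadata lacks it.
    rng_seed
        Seed for every stochastic step (ROI sampling, fixtures).
    """

    hsv_cutoffs: HsvCutoffs = field(default_factory=HsvCutoffs)
    min_region_px: int = 200
    thickness_threshold_um: float = 4.0
    max_hole_px: int = 2000
    min_strand_px: int = 5
    branch_removal_radius: int = 1
    roi_size_um: tuple[float, float] = (600.0, 400.0)
    n_rois: int = 50
    alpha: float = 0.05
    stretch_percentiles: tuple[float, float] = (1.0, 99.0)
    highpass_sigma_px: float = 10.0
    sharpness_window_px: int = 9
    pixel_size_um: Optional[float] = None
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.min_region_px < 0:
            raise ValueError("min_region_px must be non-negative")
        if self.thickness_threshold_um < 0:
            raise ValueError("thickness_threshold_um must be non-negative")
        if self.max_hole_px < 0:
            raise ValueError("max_hole_px must be non-negative")
        if self.alpha <= 0 or self.alpha >= 1:
            raise ValueError("alpha must lie in (0, 1)")
        p_lo, p_hi = self.stretch_percentiles
        if not (0 <= p_lo < p_hi <= 100):
            raise ValueError("stretch_percentiles must be an ordered pair within [0, 100]")
        if self.roi_size_um[0] <= 0 or self.roi_size_um[1] <= 0:
            raise ValueError("roi_size_um must be positive")
        if self.n_rois < 1:
            raise ValueError("n_rois must be at least 1")

    def require_pixel_size(self) -> float:
        if self.pixel_size_um is None:
            raise ValueError(
                "pixel_size_um is not set: supply it in the configuration "
                "(it is required whenever image metadata lacks a physical scale)"
            )
        return float(self.pixel_size_um)
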