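"""Synthetic UV-fluorescence tumor-surface phantoms with exhaustive ground truth.

No reference image data ship with this package, so every downstream
stage is validated against phantoms: yellow-green curvilinear collagen
ribbons with controllable length/thickness/orientation distributions
and optional crossings, purple elliptical nuclei (a fraction placed on
top of strands, to exercise hole filling), dark round vacuoles, a muted
gray cytoplasm background, Gaussian sensor noise, and — for the focus
stage — defocus stacks blurred against a tilted surface plane.

Ground truth is rendered before noise: a full structural label map,
the true per-strand parameters (length as the rasterized centerline
arc length, orientation as the best-fit line to the centerline pixels
— the same estimators the measurement stage produces, so oracle
comparisons are unambiguous), and the exact collagen pixel fraction.

Palette colors for collagen/nuclei/vacuole are validated at
construction to fall inside the corresponding HSV classification
boxes, and the cytoplasm color to fall outside all of them, so that a
noise-free phantom is classified perfectly by construction.  Note the
cytoplasm default is a desaturated gray rather than a true pink: the
collagen hue box wraps through red, so any saturated warm pink of
moderate value would legitimately classify as collagen.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.color import rgb2hsv, hsv2rgb
from skimage.draw import disk, ellipse

from .core import (
    FiberRecord,
    HsvCutoffs,
    RGBImage,
    StructureLabel,
    StructureLabelMap,
    ZStack,
    empty_fiber_table,
    make_fiber_table,
)
from .fibers import orientation_of_pixels

__all__ = [
    "DistributionSpec",
    "SurfacePlane",
    "PhantomPalette",
    "TRICHROME_PALETTE",
    "PhantomSpec",
    "PhantomGroundTruth",
    "PhantomSpecError",
    "generate_phantom",
    "generate_defocus_stack",
    "render_trichrome_reference",
]


class PhantomSpecError(ValueError):
    """Raised when a phantom specification is internally inconsistent."""


@dataclass(frozen=True)
class DistributionSpec:
    """Mean and standard deviation of a normal draw (clipped downstream)."""

    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise PhantomSpecError("distribution sd must be non-negative")


@dataclass(frozen=True)
class SurfacePlane:
    """Tissue surface height z(x, y) = z0 + gx * col + gy * row, in microns."""

    z0_um: float = 0.0
    gx_um_per_px: float = 0.0
    gy_um_per_px: float = 0.0

    def height(self, shape: tuple[int, int]) -> np.ndarray:
        rows, cols = np.indices(shape)
        return self.z0_um + self.gx_um_per_px * cols + self.gy_um_per_px * rows


def _hsv_color(h: float, s: float, v: float) -> tuple[float, float, float]:
    rgb = hsv2rgb(np.array([[[h, s, v]]], dtype=np.float64))[0, 0]
    return float(rgb[0]), float(rgb[1]), float(rgb[2])


@dataclass(frozen=True)
class PhantomPalette:
    """Flat RGB rendering colors per structural class."""

    collagen: tuple[float, float, float] = field(default_factory=lambda: _hsv_color(0.23, 0.65, 0.80))
    nuclei: tuple[float, float, float] = field(default_factory=lambda: _hsv_color(0.70, 0.55, 0.85))
    cytoplasm: tuple[float, float, float] = field(default_factory=lambda: _hsv_color(0.60, 0.30, 0.55))
    vacuole: tuple[float, float, float] = field(default_factory=lambda: _hsv_color(0.04, 0.75, 0.22))

    def as_array(self) -> np.ndarray:
        """Class-indexed (4 x 3) color lookup table."""
        lut = np.zeros((4, 3), dtype=np.float64)
        lut[int(StructureLabel.CYTOPLASM)] = self.cytoplasm
        lut[int(StructureLabel.NUCLEI)] = self.nuclei
        lut[int(StructureLabel.COLLAGEN)] = self.collagen
        lut[int(StructureLabel.VACUOLE)] = self.vacuole
        return lut

    def validate_against(self, cutoffs: HsvCutoffs) -> None:
        """Check the palette is classified correctly by the HSV boxes."""
        def hsv_of(rgb: tuple[float, float, float]) -> tuple[float, float, float]:
            h, s, v = rgb2hsv(np.array([[rgb]], dtype=np.float64))[0, 0]
            return float(h), float(s), float(v)

        for name, rgb, box in (
            ("nuclei", self.nuclei, cutoffs.nuclei),
            ("collagen", self.collagen, cutoffs.collagen),
            ("vacuole", self.vacuole, cutoffs.vacuole),
        ):
            h, s, v = hsv_of(rgb)
            if not bool(box.contains(np.array(h), np.array(s), np.array(v))):
                raise PhantomSpecError(
                    f"palette color for {name} (hsv {h:.3f},{s:.3f},{v:.3f}) "
                    f"falls outside its HSV classification box"
                )
        h, s, v = hsv_of(self.cytoplasm)
        for name, box in (("nuclei", cutoffs.nuclei), ("collagen", cutoffs.collagen), ("vacuole", cutoffs.vacuole)):
            if bool(box.contains(np.array(h), np.array(s), np.array(v))):
                raise PhantomSpecError(
                    f"cytoplasm palette color (hsv {h:.3f},{s:.3f},{v:.3f}) "
                    f"falls inside the {name} HSV box"
                )


# Masson's-trichrome-like rendering palette: blue collagen, dark purple
# nuclei, light pink cytoplasm.
TRICHROME_PALETTE = PhantomPalette(
    collagen=(0.20, 0.30, 0.75),
    nuclei=(0.25, 0.10, 0.35),
    cytoplasm=(0.95, 0.78, 0.82),
    vacuole=(0.15, 0.15, 0.15),
)


@dataclass
class PhantomSpec:
    """Generation parameters for one phantom.

    Defaults emulate the morphology the pipeline was designed for:
    dense pancreatic-tumor stroma at 0.5 um/px (the scale of a 10x
    objective filling an APS-C sensor) — a few dozen collagen
    strands with lengths mostly under ~100 um, thicknesses of a few
    microns (thin strands down to ~5 um are the interesting case),
    chaotic orientations, nucleus ellipses of roughly 12 x 8 um, and a
    low-amplitude Gaussian sensor noise.
    """

    image_size_px: tuple[int, int] = (768, 768)
    pixel_size_um: float = 0.5
    n_fibers: int = 40
    fiber_length_um: DistributionSpec = field(default_factory=lambda: DistributionSpec(60.0, 25.0))
    fiber_thickness_um: DistributionSpec = field(default_factory=lambda: DistributionSpec(8.0, 2.5))
    orientation_deg: DistributionSpec = field(default_factory=lambda: DistributionSpec(0.0, 50.0))
    crosslink_probability: float = 0.3
    n_nuclei: int = 60
    nucleus_axes_um: tuple[float, float] = (12.0, 8.0)
    nuclei_on_fiber_fraction: float = 0.4
    n_vacuoles: int = 8
    vacuole_radius_um: float = 10.0
    palette: PhantomPalette = field(default_factory=PhantomPalette)
    hsv_cutoffs: HsvCutoffs = field(default_factory=HsvCutoffs)
    noise_sd: float = 0.02
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if min(self.image_size_px) < 16:
            raise PhantomSpecError("image_size_px must be at least 16 x 16")
        if self.pixel_size_um <= 0:
            raise PhantomSpecError("pixel_size_um must be positive")
        for name in ("n_fibers", "n_nuclei", "n_vacuoles"):
            if getattr(self, name) < 0:
                raise PhantomSpecError(f"{name} must be non-negative")
        if self.fiber_length_um.mean <= 0 or self.fiber_thickness_um.mean <= 0:
            raise PhantomSpecError("fiber length and thickness means must be positive")
        if not (0.0 <= self.crosslink_probability <= 1.0):
            raise PhantomSpecError("crosslink_probability must lie in [0, 1]")
        if self.noise_sd < 0:
            raise PhantomSpecError("noise_sd must be non-negative")
        self.palette.validate_against(self.hsv_cutoffs)


@dataclass
class PhantomGroundTruth:
    """Exhaustive truth for one phantom: labels, strand table, collagen fraction."""

    label_map: StructureLabelMap
    fiber_truth: pd.DataFrame
    collagen_fraction: float

    def __post_init__(self) -> None:
        n_collagen = int(np.count_nonzero(self.label_map.labels == int(StructureLabel.COLLAGEN)))
        expected = n_collagen / self.label_map.labels.size
        if abs(self.collagen_fraction - expected) > 1e-12:
            raise ValueError("collagen_fraction inconsistent with the truth label map")


def _wrap_orientation(deg: float) -> float:
    deg = (deg + 90.0) % 180.0 - 90.0
    if deg == -90.0:
        deg = 90.0
    return deg


def _bezier_centerline(
    p0: np.ndarray, p1: np.ndarray, p2: np.ndarray
) -> tuple[np.ndarray, float]:
    """Rasterize a quadratic Bezier into a pixel chain.

    Returns the deduplicated pixel chain and the arc length of the
    continuous curve (dense polyline sum).  The continuous arc is the
    authoritative truth length: summing steps between *rounded* pixels
    would inflate the arc by the staircase detours of rasterization.
    """
    chord = np.linalg.norm(p2 - p0)
    n = max(int(4 * chord), 8)
    t = np.linspace(0.0, 1.0, n)[:, None]
    pts = (1 - t) ** 2 * p0 + 2 * t * (1 - t) * p1 + t**2 * p2
    arc = float(np.sqrt((np.diff(pts, axis=0) ** 2).sum(axis=1)).sum())
    pix = np.round(pts).astype(np.intp)
    keep = np.ones(len(pix), dtype=bool)
    keep[1:] = np.any(pix[1:] != pix[:-1], axis=1)
    return pix[keep], arc


def _paint_ribbon(canvas_shape: tuple[int, int], chain: np.ndarray, radius_px: float) -> np.ndarray:
    """Boolean ribbon mask: all pixels within radius of the centerline chain."""
    r0 = max(int(chain[:, 0].min() - radius_px - 2), 0)
    r1 = min(int(chain[:, 0].max() + radius_px + 3), canvas_shape[0])
    c0 = max(int(chain[:, 1].min() - radius_px - 2), 0)
    c1 = min(int(chain[:, 1].max() + radius_px + 3), canvas_shape[1])
    local = np.zeros((r1 - r0, c1 - c0), dtype=bool)
    local[chain[:, 0] - r0, chain[:, 1] - c0] = True
    dist = ndimage.distance_transform_edt(~local)
    mask = np.zeros(canvas_shape, dtype=bool)
    mask[r0:r1, c0:c1] = dist <= radius_px
    return mask


def _draw_fiber_geometry(
    rng: np.random.Generator,
    spec: PhantomSpec,
    shape: tuple[int, int],
    center: np.ndarray,
) -> Optional[tuple[np.ndarray, float]]:
    """One candidate fiber: returns (centerline chain, thickness_px) or None
    if the curve does not fit inside the canvas."""
    px = spec.pixel_size_um
    length_px = max(rng.normal(spec.fiber_length_um.mean, spec.fiber_length_um.sd) / px, 12.0)
    thickness_px = float(
        np.clip(rng.normal(spec.fiber_thickness_um.mean, spec.fiber_thickness_um.sd) / px, 2.0, 40.0)
    )
    theta = math.radians(_wrap_orientation(rng.normal(spec.orientation_deg.mean, spec.orientation_deg.sd)))
    # (row, col) step for angle theta against the x-axis, y-up convention
    direction = np.array([-math.sin(theta), math.cos(theta)])
    normal = np.array([-math.cos(theta), -math.sin(theta)])
    bow = rng.uniform(0.0, 0.06) * length_px * rng.choice([-1.0, 1.0])
    p0 = center - direction * length_px / 2
    p2 = center + direction * length_px / 2
    p1 = center + normal * bow * 2.0  # control point; curve midpoint bows by `bow`
    margin = thickness_px / 2 + 2
    pts = np.vstack([p0, p1, p2])
    if (
        pts[:, 0].min() < margin
        or pts[:, 1].min() < margin
        or pts[:, 0].max() >= shape[0] - margin
        or pts[:, 1].max() >= shape[1] - margin
    ):
        return None
    chain, arc_px = _bezier_centerline(p0, p1, p2)
    return chain, thickness_px, arc_px


def generate_phantom(spec: PhantomSpec) -> tuple[RGBImage, PhantomGroundTruth]:
    """Generate one phantom image plus its ground truth.

    Deterministic for a fixed ``rng_seed``.  Fibers are painted first;
    nuclei are painted afterwards and may occlude strands (a fraction
    is deliberately centered on collagen pixels), which is what the
    hole-filling stage of segmentation has to undo.  With
    ``crosslink_probability`` 0 fibers are placed mutually disjoint
    with a small margin; with probability p a fiber is instead seeded
    on an existing strand to form a crossing.
    """
    rng = np.random.default_rng(spec.rng_seed)
    shape = tuple(spec.image_size_px)
    labels = np.full(shape, int(StructureLabel.CYTOPLASM), dtype=np.uint8)
    collagen = np.zeros(shape, dtype=bool)
    occupied = np.zeros(shape, dtype=bool)  # collagen dilated by a separation margin
    px = spec.pixel_size_um

    records: list[FiberRecord] = []
    for i in range(spec.n_fibers):
        crossing = collagen.any() and (rng.random() < spec.crosslink_probability)
        placed = False
        for _attempt in range(300):
            if crossing:
                rows, cols = np.nonzero(collagen)
                k = rng.integers(len(rows))
                center = np.array([float(rows[k]), float(cols[k])])
                center += rng.normal(0.0, 2.0, size=2)
            else:
                center = np.array(
                    [rng.uniform(0, shape[0] - 1), rng.uniform(0, shape[1] - 1)]
                )
            geom = _draw_fiber_geometry(rng, spec, shape, center)
            if geom is None:
                continue
            chain, thickness_px, arc_px = geom
            ribbon = _paint_ribbon(shape, chain, thickness_px / 2)
            if not crossing and (ribbon & occupied).any():
                continue
            collagen |= ribbon
            occupied |= ndimage.binary_dilation(ribbon, iterations=3)
            records.append(
                FiberRecord(
                    strand_id=i,
                    length_um=arc_px * px,
                    thickness_um=thickness_px * px,
                    orientation_deg=orientation_of_pixels(chain),
                    n_pixels=int(len(chain)),
                    centroid_row=float(chain[:, 0].mean()),
                    centroid_col=float(chain[:, 1].mean()),
                )
            )
            placed = True
            break
        if not placed:
            raise PhantomSpecError(
                f"could not place fiber {i}: the canvas is too crowded for the "
                f"requested fiber count/size at this image size"
            )
    labels[collagen] = int(StructureLabel.COLLAGEN)

    # vacuoles: dark round holes on cytoplasm, kept clear of collagen
    r_vac = max(spec.vacuole_radius_um / px, 2.0)
    for _ in range(spec.n_vacuoles):
        for _attempt in range(100):
            center = (rng.uniform(r_vac, shape[0] - r_vac), rng.uniform(r_vac, shape[1] - r_vac))
            rr, cc = disk(center, r_vac, shape=shape)
            if (labels[rr, cc] == int(StructureLabel.CYTOPLASM)).all():
                labels[rr, cc] = int(StructureLabel.VACUOLE)
                break

    # nuclei: ellipses, painted last so some occlude collagen strands
    a_px = max(spec.nucleus_axes_um[0] / (2 * px), 1.5)
    b_px = max(spec.nucleus_axes_um[1] / (2 * px), 1.5)
    for _ in range(spec.n_nuclei):
        on_fiber = collagen.any() and (rng.random() < spec.nuclei_on_fiber_fraction)
        if on_fiber:
            rows, cols = np.nonzero(collagen)
            k = rng.integers(len(rows))
            center = (float(rows[k]), float(cols[k]))
        else:
            center = (rng.uniform(a_px, shape[0] - a_px), rng.uniform(a_px, shape[1] - a_px))
        rr, cc = ellipse(center[0], center[1], a_px, b_px, shape=shape, rotation=rng.uniform(0, math.pi))
        labels[rr, cc] = int(StructureLabel.NUCLEI)

    label_map = StructureLabelMap(labels)
    fraction = float(np.count_nonzero(labels == int(StructureLabel.COLLAGEN))) / labels.size
    truth = PhantomGroundTruth(
        label_map=label_map,
        fiber_truth=make_fiber_table(records) if records else empty_fiber_table(),
        collagen_fraction=fraction,
    )

    lut = spec.palette.as_array()
    pixels = lut[labels]
    if spec.noise_sd > 0:
        pixels = pixels + rng.normal(0.0, spec.noise_sd, size=pixels.shape)
    image = RGBImage(np.clip(pixels, 0.0, 1.0), px)
    return image, truth


def generate_defocus_stack(
    image: RGBImage,
    n_slices: int = 7,
    z_step_um: float = 6.3,
    blur_per_um: float = 0.25,
    surface: SurfacePlane = SurfacePlane(),
) -> ZStack:
    """Blur a sharp phantom against a surface plane into a defocus z-stack.

    Slice i sits at depth ``i * z_step_um``; each pixel of slice i is
    the sharp image blurred with a Gaussian of sigma
    ``blur_per_um * |z_i - z_surface(x, y)|`` pixels.  A flat surface
    lying exactly at a slice depth makes that slice equal the sharp
    input.  Spatially varying sigma is realized by interpolating
    between a ladder of uniformly blurred copies.
    """
    if n_slices < 1:
        raise ValueError("n_slices must be at least 1")
    if blur_per_um < 0:
        raise ValueError("blur_per_um must be non-negative")
    shape = image.shape
    height = surface.height(shape)
    slices = []
    for i in range(n_slices):
        sigma_map = blur_per_um * np.abs(i * z_step_um - height)
        if blur_per_um == 0 or float(sigma_map.max()) == 0.0:
            slices.append(image.copy())
            continue
        if float(sigma_map.max() - sigma_map.min()) < 1e-12:
            sigma = float(sigma_map.flat[0])
            blurred = np.stack(
                [ndimage.gaussian_filter(image.pixels[..., c], sigma, mode="nearest") for c in range(3)],
                axis=-1,
            )
            slices.append(RGBImage(np.clip(blurred, 0, 1), image.pixel_size_um))
            continue
        levels = np.linspace(0.0, float(sigma_map.max()), 9)
        ladder = [image.pixels]
        for sig in levels[1:]:
            ladder.append(
                np.stack(
                    [ndimage.gaussian_filter(image.pixels[..., c], sig, mode="nearest") for c in range(3)],
                    axis=-1,
                )
            )
        ladder_arr = np.stack(ladder, axis=0)
        idx = np.clip(sigma_map / levels[-1] * (len(levels) - 1), 0, len(levels) - 1)
        lo = np.floor(idx).astype(np.intp)
        hi = np.minimum(lo + 1, len(levels) - 1)
        w = (idx - lo)[..., None]
        rows, cols = np.indices(shape)
        blurred = (1 - w) * ladder_arr[lo, rows, cols] + w * ladder_arr[hi, rows, cols]
        slices.append(RGBImage(np.clip(blurred, 0, 1), image.pixel_size_um))
    return ZStack(slices, z_step_um=z_step_um)


def render_trichrome_reference(
    truth: PhantomGroundTruth,
    pixel_size_um: float = 1.0,
    palette: PhantomPalette = TRICHROME_PALETTE,
    noise_sd: float = 0.01,
    rng_seed: int = 0,
) -> RGBImage:
    """Render the truth geometry in a trichrome-stain-like palette.

    Structure-wise flat colors (blue collagen, dark purple nuclei,
    light pink cytoplasm) plus mild Gaussian noise; serves as the
    reference image for color-transfer statistics.
    """
    rng = np.random.default_rng(rng_seed)
    lut = palette.as_array()
    pixels = lut[truth.label_map.labels]
    if noise_sd > 0:
        pixels = pixels + rng.normal(0.0, noise_sd, size=pixels.shape)
    return RGBImage(np.clip(pixels, 0.0, 1.0), pixel_size_um)
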