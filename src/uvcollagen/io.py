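"""File I/O: images, z-stacks, label maps, fiber tables, configuration.

TIFF is the native image format (pixel size is stored in the resolution
tags); PNG is supported for display-oriented outputs.  Fiber tables are
plain CSV with the fixed exchange header, and run configuration is
YAML mirroring :class:`~uvcollagen.core.AnalysisConfig`.
"""

from __future__ import annotations

import dataclasses
import os
from pathlib import Path
from typing import Optional, Sequence, Union

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
import yaml
from PIL import Image

from .core import (
    FIBER_COLUMNS,
    AnalysisConfig,
    ClassCutoff,
    HsvCutoffs,
    RGBImage,
    StructureLabel,
    StructureLabelMap,
    ZStack,
    empty_fiber_table,
)

__all__ = [
    "read_image",
    "write_image",
    "read_zstack",
    "write_zstack",
    "write_fiber_table",
    "read_fiber_table",
    "write_label_map",
    "read_label_map",
    "load_config",
    "save_config",
    "FormatError",
]

PathLike = Union[str, os.PathLike]

# Fixed legend for paletted label-map PNGs (class index -> display RGB).
LABEL_PALETTE: dict[StructureLabel, tuple[int, int, int]] = {
    StructureLabel.CYTOPLASM: (205, 183, 181),
    StructureLabel.NUCLEI: (120, 60, 170),
    StructureLabel.COLLAGEN: (140, 190, 60),
    StructureLabel.VACUOLE: (25, 25, 25),
}


class FormatError(ValueError):
    """Raised when a file does not satisfy the expected image contract."""


def _pixel_size_from_tiff(path: Path) -> Optional[float]:
    """Extract microns-per-pixel from TIFF resolution tags, if present."""
    try:
        with tifffile.TiffFile(str(path)) as tf:
            page = tf.pages[0]
            xres = page.tags.get("XResolution")
            unit = page.tags.get("ResolutionUnit")
            if xres is None or unit is None:
                return None
            num, den = xres.value
            if num == 0:
                return None
            px_per_unit = num / den
            # unit code: 2 = inch, 3 = centimeter
            unit_um = {2: 25400.0, 3: 10000.0}.get(int(unit.value))
            if unit_um is None:
                return None
            return unit_um / px_per_unit
    except (tifffile.TiffFileError, OSError, ValueError):
        return None


def read_image(path: PathLike, pixel_size_um: Optional[float] = None) -> RGBImage:
    """Read a TIFF or PNG image as an :class:`RGBImage` scaled to [0, 1].

    Integer data are divided by the dtype maximum.  The pixel size is
    taken from TIFF resolution metadata when present; otherwise
    ``pixel_size_um`` must be supplied — there is no silent default.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    arr = iio.imread(path)
    if arr.ndim == 3 and arr.shape[2] == 4:  # tolerate opaque alpha
        if not np.all(arr[..., 3] == arr[..., 3].flat[0]):
            raise FormatError(f"{path}: RGBA with a non-constant alpha channel is not supported")
        arr = arr[..., :3]
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise FormatError(f"{path}: expected a 3-channel image, got shape {arr.shape}")
    if np.issubdtype(arr.dtype, np.integer):
        info = np.iinfo(arr.dtype)
        pixels = arr.astype(np.float64) / info.max
    else:
        pixels = arr.astype(np.float64)
        if pixels.min() < 0 or pixels.max() > 1:
            raise FormatError(f"{path}: float image values must already lie in [0, 1]")
    meta_px = _pixel_size_from_tiff(path) if path.suffix.lower() in (".tif", ".tiff") else None
    px = meta_px if meta_px is not None else pixel_size_um
    if px is None:
        raise ValueError(
            f"{path}: no pixel size in metadata; pass pixel_size_um explicitly"
        )
    return RGBImage(np.clip(pixels, 0.0, 1.0), px)


def write_image(image: RGBImage, path: PathLike, dtype: str = "uint8") -> None:
    """Write an image as 8- or 16-bit TIFF/PNG.

    TIFF output records the pixel size in the resolution tags so that
    :func:`read_image` round-trips it.
    """
    path = Path(path)
    if dtype == "uint8":
        arr = np.round(image.pixels * 255.0).astype(np.uint8)
    elif dtype == "uint16":
        arr = np.round(image.pixels * 65535.0).astype(np.uint16)
    else:
        raise ValueError(f"unsupported dtype {dtype!r}; use 'uint8' or 'uint16'")
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix.lower() in (".tif", ".tiff"):
        px_per_cm = 10000.0 / image.pixel_size_um
        tifffile.imwrite(
            str(path), arr, resolution=(px_per_cm, px_per_cm), resolutionunit="CENTIMETER"
        )
    else:
        iio.imwrite(path, arr)


def read_zstack(
    paths: Sequence[PathLike],
    z_step_um: float = 6.3,
    pixel_size_um: Optional[float] = None,
) -> ZStack:
    """Read an ordered list of same-shape slices into a :class:`ZStack`."""
    if len(paths) < 1:
        raise ValueError("a z-stack needs at least one slice path")
    slices = [read_image(p, pixel_size_um=pixel_size_um) for p in paths]
    shape0 = slices[0].shape
    for p, s in zip(paths, slices):
        if s.shape != shape0:
            raise FormatError(f"{p}: slice shape {s.shape} differs from first slice {shape0}")
    return ZStack(slices, z_step_um=z_step_um)


def write_zstack(stack: ZStack, directory: PathLike, prefix: str = "slice") -> list[Path]:
    """Write each slice as ``<prefix>_<i>.tif``; returns written paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    out = []
    for i, s in enumerate(stack.slices):
        p = directory / f"{prefix}_{i:02d}.tif"
        write_image(s, p)
        out.append(p)
    return out


def write_fiber_table(table: pd.DataFrame, path: PathLike) -> None:
    """Write a fiber table as CSV with the fixed exchange header.

    Only the canonical columns are written; floats carry six significant
    digits, enough for lossless desk-scale round trips.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    missing = [c for c in FIBER_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"fiber table is missing columns {missing}")
    table[FIBER_COLUMNS].to_csv(path, index=False, float_format="%.6g")


def read_fiber_table(path: PathLike) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path)
    if list(df.columns) != FIBER_COLUMNS:
        raise FormatError(f"{path}: unexpected fiber-table header {list(df.columns)}")
    if df.empty:
        return empty_fiber_table()[FIBER_COLUMNS]
    return df.astype(
        {
            "strand_id": np.int64,
            "length_um": np.float64,
            "thickness_um": np.float64,
            "orientation_deg": np.float64,
            "n_pixels": np.int64,
        }
    )


def write_label_map(label_map: StructureLabelMap, path: PathLike) -> None:
    """Write a label map as a paletted PNG with the fixed class legend."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = Image.fromarray(label_map.labels, mode="P")
    palette = [0] * (256 * 3)
    for lab, rgb in LABEL_PALETTE.items():
        palette[3 * int(lab) : 3 * int(lab) + 3] = list(rgb)
    img.putpalette(palette)
    img.save(path)
    if label_map.necrosis_mask is not None:
        necro = Image.fromarray(label_map.necrosis_mask.astype(np.uint8) * 255, mode="L")
        necro.save(path.with_suffix(".necrosis.png"))


def read_label_map(path: PathLike) -> StructureLabelMap:
    path = Path(path)
    img = Image.open(path)
    if img.mode != "P":
        raise FormatError(f"{path}: expected a paletted label PNG")
    labels = np.asarray(img, dtype=np.uint8)
    necro_path = path.with_suffix(".necrosis.png")
    necrosis = None
    if necro_path.exists():
        necrosis = np.asarray(Image.open(necro_path), dtype=np.uint8) > 0
    return StructureLabelMap(labels, necrosis)


def _cutoffs_to_dict(c: HsvCutoffs) -> dict:
    return {
        name: {"h": list(box.h), "s": list(box.s), "v": list(box.v)}
        for name, box in (("nuclei", c.nuclei), ("collagen", c.collagen), ("vacuole", c.vacuole))
    }


def _cutoffs_from_dict(d: dict) -> HsvCutoffs:
    def box(name: str) -> ClassCutoff:
        b = d[name]
        return ClassCutoff(h=tuple(b["h"]), s=tuple(b["s"]), v=tuple(b["v"]))

    return HsvCutoffs(nuclei=box("nuclei"), collagen=box("collagen"), vacuole=box("vacuole"))


def save_config(config: AnalysisConfig, path: PathLike) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    d = dataclasses.asdict(config)
    d["hsv_cutoffs"] = _cutoffs_to_dict(config.hsv_cutoffs)
    d["roi_size_um"] = list(config.roi_size_um)
    d["stretch_percentiles"] = list(config.stretch_percentiles)
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)


def load_config(path: PathLike) -> AnalysisConfig:
    path = Path(path)
    with open(path) as fh:
        d = yaml.safe_load(fh)
    if not isinstance(d, dict):
        raise FormatError(f"{path}: configuration must be a mapping")
    if "hsv_cutoffs" in d and d["hsv_cutoffs"] is not None:
        d["hsv_cutoffs"] = _cutoffs_from_dict(d["hsv_cutoffs"])
    for key in ("roi_size_um", "stretch_percentiles"):
        if key in d and d[key] is not None:
            d[key] = tuple(d[key])
    known = {f.name for f in dataclasses.fields(AnalysisConfig)}
    unknown = set(d) - known
    if unknown:
        raise FormatError(f"{path}: unknown configuration fields {sorted(unknown)}")
    return AnalysisConfig(**d)
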