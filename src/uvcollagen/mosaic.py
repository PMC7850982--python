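"""Tile stitching for whole-specimen mosaics acquired with nominal overlap.

Motorized-stage acquisition with ~10% tile overlap justifies a purely
translational model: tile placement starts from the nominal grid step,
each adjacent pair's shift is refined by maximizing the normalized
cross-correlation (NCC) of their overlap strips within a small search
window, placements are chained row-major, and tiles are blended with
linear feathering across the overlap so exact alignments reconstruct
the specimen exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .core import RGBImage

__all__ = ["TileGrid", "plan_grid", "cut_into_tiles", "refine_offsets", "blend"]

logger = logging.getLogger(__name__)


def plan_grid(
    specimen_size_px: tuple[int, int],
    tile_size_px: tuple[int, int],
    overlap_frac: float,
) -> np.ndarray:
    """Nominal tile origins covering a specimen, as an (R, C, 2) array.

    Origins are spaced by ``tile_size * (1 - overlap_frac)``; the last
    row and column are clamped so the plan covers every specimen pixel.
    """
    if not (0.0 <= overlap_frac < 0.5):
        raise ValueError(f"overlap_frac must lie in [0, 0.5), got {overlap_frac}")
    sh, sw = specimen_size_px
    th, tw = tile_size_px
    if th > sh or tw > sw:
        raise ValueError("tile larger than specimen")

    def axis_origins(extent: int, tile: int) -> list[int]:
        step = max(int(round(tile * (1.0 - overlap_frac))), 1)
        origins = list(range(0, max(extent - tile, 0) + 1, step))
        if origins[-1] + tile < extent:
            origins.append(extent - tile)
        return origins

    rows = axis_origins(sh, th)
    cols = axis_origins(sw, tw)
    grid = np.zeros((len(rows), len(cols), 2), dtype=np.intp)
    for i, r in enumerate(rows):
        for j, c in enumerate(cols):
            grid[i, j] = (r, c)
    return grid


@dataclass
class TileGrid:
    """A 2-D array of same-shape tiles with nominal overlap and refined offsets.

    ``offsets[r, c]`` is the refinement (drow, dcol) of tile (r, c)'s
    step relative to its chaining neighbor — zero until
    :func:`refine_offsets` runs.
    """

    tiles: list[list[RGBImage]]
    nominal_overlap_frac: float
    offsets: Optional[np.ndarray] = None
    search_radius_px: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.nominal_overlap_frac < 0.5):
            raise ValueError("nominal_overlap_frac must lie in [0, 0.5)")
        shape0 = self.tiles[0][0].shape
        ncols = len(self.tiles[0])
        for row in self.tiles:
            if len(row) != ncols:
                raise ValueError("ragged tile grid")
            for t in row:
                if t.shape != shape0:
                    raise ValueError("all tiles must share one shape")
        if self.offsets is None:
            self.offsets = np.zeros((len(self.tiles), ncols, 2), dtype=np.intp)
        self.offsets = np.asarray(self.offsets, dtype=np.intp)
        if self.offsets.shape != (len(self.tiles), ncols, 2):
            raise ValueError("offsets shape must be (rows, cols, 2)")

    @property
    def grid_shape(self) -> tuple[int, int]:
        return len(self.tiles), len(self.tiles[0])

    @property
    def tile_shape(self) -> tuple[int, int]:
        return self.tiles[0][0].shape

    def nominal_step(self) -> tuple[int, int]:
        th, tw = self.tile_shape
        return (
            max(int(round(th * (1.0 - self.nominal_overlap_frac))), 1),
            max(int(round(tw * (1.0 - self.nominal_overlap_frac))), 1),
        )

    def origins(self) -> np.ndarray:
        """Absolute tile origins after chaining nominal steps + offsets.

        Chaining is row-major: tile (r, 0) hangs off tile (r-1, 0);
        tile (r, c>0) hangs off its left neighbor.
        """
        nrows, ncols = self.grid_shape
        step_r, step_c = self.nominal_step()
        origins = np.zeros((nrows, ncols, 2), dtype=np.intp)
        for r in range(nrows):
            for c in range(ncols):
                if r == 0 and c == 0:
                    continue
                if c == 0:
                    origins[r, c] = origins[r - 1, c] + (step_r, 0) + self.offsets[r, c]
                else:
                    origins[r, c] = origins[r, c - 1] + (0, step_c) + self.offsets[r, c]
        return origins


def cut_into_tiles(
    image: RGBImage,
    grid_shape: tuple[int, int],
    overlap_frac: float = 0.10,
    jitter_px: int = 0,
    rng: Optional[np.random.Generator] = None,
) -> tuple[TileGrid, np.ndarray]:
    """Cut a whole image into an overlapping tile grid (fixture helper).

    Tile size is chosen so the grid at the nominal overlap spans the
    image.  With ``jitter_px > 0``, every non-anchor tile is cut from
    its nominal origin plus a uniform integer jitter in
    ``[-jitter_px, jitter_px]`` — the grid still *claims* nominal
    placement, so offset refinement must rediscover the jitter.
    Returns the grid and the true per-tile cut origins.
    """
    nrows, ncols = grid_shape
    h, w = image.shape
    rng = rng or np.random.default_rng(0)

    def tile_extent(extent: int, n: int) -> int:
        # n tiles of size t with step t*(1-f) span t*(1+(n-1)*(1-f)) = extent
        return int(np.floor(extent / (1.0 + (n - 1) * (1.0 - overlap_frac))))

    th, tw = tile_extent(h, nrows), tile_extent(w, ncols)
    step_r = max(int(round(th * (1.0 - overlap_frac))), 1)
    step_c = max(int(round(tw * (1.0 - overlap_frac))), 1)
    tiles: list[list[RGBImage]] = []
    true_origins = np.zeros((nrows, ncols, 2), dtype=np.intp)
    for r in range(nrows):
        row = []
        for c in range(ncols):
            r0, c0 = r * step_r, c * step_c
            if jitter_px > 0 and not (r == 0 and c == 0):
                r0 += int(rng.integers(-jitter_px, jitter_px + 1))
                c0 += int(rng.integers(-jitter_px, jitter_px + 1))
            r0 = int(np.clip(r0, 0, h - th))
            c0 = int(np.clip(c0, 0, w - tw))
            true_origins[r, c] = (r0, c0)
            row.append(RGBImage(image.pixels[r0 : r0 + th, c0 : c0 + tw].copy(), image.pixel_size_um))
        tiles.append(row)
    return TileGrid(tiles, overlap_frac), true_origins


def _luma(img: RGBImage) -> np.ndarray:
    return img.pixels @ np.array([0.2126, 0.7152, 0.0722])


def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a * a).sum() * (b * b).sum())
    if denom == 0:
        return np.nan
    return float((a * b).sum() / denom)


def _refine_pair(
    fixed: np.ndarray, moving: np.ndarray, nominal: tuple[int, int], radius: int
) -> Optional[tuple[int, int]]:
    """Best (drow, dcol) refinement of `moving` relative to `fixed`.

    ``nominal`` is the nominal origin of `moving` in `fixed`'s frame.
    Scores the NCC of the overlap region for every integer shift within
    the search square; returns None when every overlap is textureless.
    """
    h, w = fixed.shape
    mh, mw = moving.shape
    best, best_score = None, -np.inf
    for dr in range(-radius, radius + 1):
        for dc in range(-radius, radius + 1):
            r0, c0 = nominal[0] + dr, nominal[1] + dc
            fr0, fc0 = max(r0, 0), max(c0, 0)
            fr1, fc1 = min(r0 + mh, h), min(c0 + mw, w)
            if fr1 - fr0 < 4 or fc1 - fc0 < 4:
                continue
            sub_f = fixed[fr0:fr1, fc0:fc1]
            sub_m = moving[fr0 - r0 : fr1 - r0, fc0 - c0 : fc1 - c0]
            score = _ncc(sub_f, sub_m)
            if np.isnan(score):
                continue
            if score > best_score:
                best_score, best = score, (dr, dc)
    return best


def refine_offsets(grid: TileGrid, search_radius_px: int = 5) -> TileGrid:
    """Refine each tile's step against its chaining neighbor by NCC.

    Flat (textureless) overlap strips fall back to the nominal offset
    with a warning.  Offsets never exceed the search radius.
    """
    nrows, ncols = grid.grid_shape
    step_r, step_c = grid.nominal_step()
    offsets = np.zeros((nrows, ncols, 2), dtype=np.intp)
    lumas = [[_luma(t) for t in row] for row in grid.tiles]
    for r in range(nrows):
        for c in range(ncols):
            if r == 0 and c == 0:
                continue
            if c == 0:
                fixed, nominal = lumas[r - 1][c], (step_r, 0)
            else:
                fixed, nominal = lumas[r][c - 1], (0, step_c)
            found = _refine_pair(fixed, lumas[r][c], nominal, search_radius_px)
            if found is None:
                logger.warning("tile (%d, %d): textureless overlap, using nominal offset", r, c)
                found = (0, 0)
            offsets[r, c] = found
    return TileGrid(grid.tiles, grid.nominal_overlap_frac, offsets, search_radius_px)


def blend(grid: TileGrid) -> RGBImage:
    """Feather-blend the grid into one mosaic at its refined placement.

    Per-tile weights ramp linearly from the tile border over the
    nominal overlap width, so overlap regions cross-fade and identical
    overlapping content reconstructs exactly; pixels covered by a
    single tile are copied verbatim.
    """
    origins = grid.origins()
    origins = origins - origins.reshape(-1, 2).min(axis=0)
    th, tw = grid.tile_shape
    step_r, step_c = grid.nominal_step()
    ramp_r = max(th - step_r, 1)
    ramp_c = max(tw - step_c, 1)
    extent = origins.reshape(-1, 2).max(axis=0) + (th, tw)
    acc = np.zeros((extent[0], extent[1], 3), dtype=np.float64)
    wsum = np.zeros((extent[0], extent[1]), dtype=np.float64)

    def ramp(n: int, length: int) -> np.ndarray:
        x = np.arange(n, dtype=np.float64)
        return np.minimum.reduce([np.ones(n), (x + 1) / length, (n - x) / length])

    weight = ramp(th, ramp_r)[:, None] * ramp(tw, ramp_c)[None, :]
    nrows, ncols = grid.grid_shape
    for r in range(nrows):
        for c in range(ncols):
            r0, c0 = origins[r, c]
            acc[r0 : r0 + th, c0 : c0 + tw] += weight[..., None] * grid.tiles[r][c].pixels
            wsum[r0 : r0 + th, c0 : c0 + tw] += weight
    out = np.divide(acc, wsum[..., None], out=np.zeros_like(acc), where=wsum[..., None] > 0)
    return RGBImage(np.clip(out, 0.0, 1.0), grid.tiles[0][0].pixel_size_um)
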