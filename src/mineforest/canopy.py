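"""Canopy-weighted forest-loss metrics.

Turns fine-resolution tree-cover / loss-year rasters into the response used
by the outcome analysis: yearly tree-canopy area lost (m^2) per 1 km^2
analysis pixel, weighting each cleared cell by its canopy fraction so that
clearing dense forest counts for more than clearing sparse woodland. An
unweighted variant ("forest area lost", the Global-Forest-Watch-style
number) is produced alongside, as are the mean and SD of tree cover over
the forested part of each pixel.

Processing stages mirror the raster workflow:

1. ``yearly_cover_bands`` — per-year canopy cover at fine resolution,
2. ``aggregate_blocks``   — intermediate ~half-hectare blocks with a >= 10%
   forest mask (the working definition of forest) and yearly loss
   proportions,
3. ``canopy_loss_pixels`` — pixel-level m^2 lost per year, canopy-weighted
   by the cover immediately *before* the loss (band t-1; a cell cleared in
   year t already has zero cover in band t).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grids import FineRasterStack

__all__ = [
    "yearly_cover_bands",
    "aggregate_blocks",
    "canopy_loss_pixels",
    "unweighted_forest_loss",
    "BlockAggregate",
    "FOREST_COVER_THRESHOLD",
]

FOREST_COVER_THRESHOLD = 10.0  # percent cover at block scale defining forest


def yearly_cover_bands(stack: FineRasterStack, n_years: int | None = None) -> np.ndarray:
    """Per-year fine-resolution canopy cover, shape (n_years+1, ny, nx).

    Band 0 is the year-0 tree cover; band t keeps a cell's cover while it
    is unlost (lossyear == 0 or lossyear > t) and zeroes it from its loss
    year onwards.
    """
    if n_years is None:
        n_years = stack.n_years
    tc = stack.treecover2000
    ly = stack.lossyear
    t = np.arange(n_years + 1)[:, None, None]
    alive = (ly == 0) | (ly > t)
    return np.where(alive, tc, 0.0)


def _block_reduce_mean(arr: np.ndarray, edge: int) -> np.ndarray:
    """Mean over non-overlapping edge x edge tiles of the last two axes."""
    *lead, ny, nx = arr.shape
    if ny % edge or nx % edge:
        raise ValueError("grid shape is not divisible by the block edge")
    return arr.reshape(*lead, ny // edge, edge, nx // edge, edge).mean(axis=(-3, -1))


@dataclass
class BlockAggregate:
    """Half-hectare-scale aggregation of the fine rasters.

    ``cover`` has shape (n_years+1, nby, nbx) in percent; ``loss_prop`` has
    shape (n_years, nby, nbx) giving the fraction of the block first lost in
    each year (year index 0 == year 1); ``forest_mask`` flags blocks at or
    above the 10% year-0 cover threshold. ``block_area`` is in m^2.
    """

    cover: np.ndarray
    loss_prop: np.ndarray
    forest_mask: np.ndarray
    block_size: float
    block_area: float
    origin: tuple[float, float]

    @property
    def n_years(self) -> int:
        return self.loss_prop.shape[0]


def aggregate_blocks(
    stack: FineRasterStack,
    block_edge_cells: int = 4,
    n_years: int | None = None,
    forest_threshold: float = FOREST_COVER_THRESHOLD,
) -> BlockAggregate:
    """Aggregate cover bands and loss indicators to the block scale.

    Blocks are ``block_edge_cells`` x ``block_edge_cells`` squares of fine
    cells (equal-area cells, so the area-weighted mean is the plain mean).
    Blocks whose year-0 cover is below ``forest_threshold`` percent are
    masked out of every downstream sum.
    """
    if n_years is None:
        n_years = stack.n_years
    tc, ly = stack.treecover2000, stack.lossyear
    # band-by-band aggregation keeps peak memory at one fine grid
    cover = np.stack(
        [
            _block_reduce_mean(np.where((ly == 0) | (ly > t), tc, 0.0), block_edge_cells)
            for t in range(n_years + 1)
        ]
    )
    loss_prop = np.stack(
        [
            _block_reduce_mean((ly == t).astype(float), block_edge_cells)
            for t in range(1, n_years + 1)
        ]
    )
    mask = cover[0] >= forest_threshold
    size = block_edge_cells * stack.cell_size
    return BlockAggregate(
        cover=cover,
        loss_prop=loss_prop,
        forest_mask=mask,
        block_size=size,
        block_area=size * size,
        origin=stack.origin,
    )


def canopy_loss_pixels(blocks: BlockAggregate, pixel_size: float = 1000.0) -> pd.DataFrame:
    """Canopy-weighted and unweighted loss per analysis pixel and year.

    Per pixel-year t (1-based):

    * ``canopy_loss_Y{t}``: sum over unmasked blocks inside the pixel of
      block_area x loss_proportion(t) x cover_fraction(t-1), the m^2 of
      tree canopy cleared;
    * ``forest_loss_Y{t}``: the same with the cover weight replaced by 1 —
      m^2 of forest area cleared;
    * ``mean_treecover`` / ``sd_treecover``: year-0 cover statistics over
      unmasked (forested) blocks only.

    Pixels containing no forested block get NaN cover statistics and are
    flagged ``forest = False``.
    """
    factor = pixel_size / blocks.block_size
    if abs(factor - round(factor)) > 1e-9:
        raise ValueError("pixel size is not an integer multiple of the block size")
    factor = int(round(factor))
    n_years = blocks.n_years
    nby, nbx = blocks.forest_mask.shape
    if nby % factor or nbx % factor:
        raise ValueError("block grid does not tile into whole pixels")
    npy, npx = nby // factor, nbx // factor

    def pixel_sum(a):
        return a.reshape(-1, npy, factor, npx, factor).sum(axis=(2, 4))

    mask = blocks.forest_mask.astype(float)
    cover_frac = blocks.cover / 100.0
    weighted = blocks.loss_prop * cover_frac[:-1] * mask  # (T, nby, nbx)
    unweighted = blocks.loss_prop * mask

    canopy_loss = pixel_sum(weighted) * blocks.block_area  # (T, npy, npx)
    forest_loss = pixel_sum(unweighted) * blocks.block_area

    n_forest = pixel_sum(mask[None])[0]
    with np.errstate(invalid="ignore", divide="ignore"):
        cov0 = blocks.cover[0]
        mean_tc = pixel_sum((cov0 * mask)[None])[0] / n_forest
        mean_sq = pixel_sum((cov0**2 * mask)[None])[0] / n_forest
        sd_tc = np.sqrt(np.maximum(mean_sq - mean_tc**2, 0.0))
    forest = n_forest > 0
    mean_tc = np.where(forest, mean_tc, np.nan)
    sd_tc = np.where(forest, sd_tc, np.nan)

    rows, cols = np.divmod(np.arange(npy * npx), npx)
    out = pd.DataFrame(
        {
            "pixel_id": np.arange(npy * npx),
            "x": blocks.origin[0] + (cols + 0.5) * pixel_size,
            "y": blocks.origin[1] + (rows + 0.5) * pixel_size,
            "forest": forest.ravel(),
            "mean_treecover": mean_tc.ravel(),
            "sd_treecover": sd_tc.ravel(),
        }
    )
    for t in range(1, n_years + 1):
        out[f"canopy_loss_Y{t}"] = canopy_loss[t - 1].ravel()
        out[f"forest_loss_Y{t}"] = forest_loss[t - 1].ravel()
    return out


def unweighted_forest_loss(blocks: BlockAggregate, pixel_size: float = 1000.0) -> pd.DataFrame:
    """Forest area lost (m^2) per pixel-year: the Global-Forest-Watch-style
    variant where every unmasked cleared block counts at weight 1.

    A narrowed view of :func:`canopy_loss_pixels`; the weighted and
    unweighted columns are computed in one pass there.
    """
    full = canopy_loss_pixels(blocks, pixel_size)
    keep = ["pixel_id", "x", "y", "forest"] + [
        c for c in full.columns if c.startswith("forest_loss_")
    ]
    return full[keep]
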