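"""Per-mine study-frame construction.

For each newly active mining lease this module rasterises "treatment"
(lease + radial buffer) onto the 1 km^2 analysis lattice, carves the
candidate-control pool out of exploration leases, thins both with a
systematic subsample (which also removes direct pixel neighbours), applies
the forest and same-region filters, and attaches the outcome years and the
pre-treatment-loss confounder. The result, one ``StudyFrame`` per mine, is
the input to statistical matching.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import box
from shapely.ops import unary_union

from .canopy import FOREST_COVER_THRESHOLD
from .grids import pixel_grid
from .landscape import LML, LEL, SSL, LandscapeConfig, Lease, LeaseSet

__all__ = [
    "StudyDesignError",
    "treated_mask",
    "control_pool",
    "systematic_subsample",
    "assemble_frame",
]

SSL_BUFFER = 5_000.0  # small-scale leases are excluded with a 5 km halo

CONFOUNDERS = [
    "mean_treecover", "sd_treecover", "dist_road", "elevation", "slope",
    "popdens", "burned", "aez", "protected", "pre_loss",
]


class StudyDesignError(RuntimeError):
    """A mine's frame cannot be built under the configured filters."""


def _pixel_boxes(config: LandscapeConfig):
    pid, px, py, n_rows, n_cols = pixel_grid(config.width, config.height, config.pixel_size)
    half = config.pixel_size / 2.0
    boxes = shapely.box(px - half, py - half, px + half, py + half)
    return pid, boxes, n_rows, n_cols


def _pixels_touching(geom, config: LandscapeConfig) -> np.ndarray:
    """Pixel ids whose square intersects ``geom`` with positive area."""
    if geom.is_empty:
        return np.array([], dtype=int)
    pid, boxes, _, _ = _pixel_boxes(config)
    cand = shapely.intersects(boxes, geom)
    if not cand.any():
        return np.array([], dtype=int)
    areas = shapely.area(shapely.intersection(boxes[cand], geom))
    out = pid[cand][areas > 0]
    return out


def treated_mask(lease: Lease, config: LandscapeConfig,
                 buffer_distance: float | None = None) -> np.ndarray:
    """Pixels treated by one mine: squares positively intersecting the
    buffered lease polygon. Treatment is binary; overlaps with other mines'
    buffers are ignored."""
    if lease.lease_type != LML or lease.active_from is None:
        raise ValueError("treated_mask expects an active mining lease")
    dist = config.buffer_distance if buffer_distance is None else buffer_distance
    if dist < 0:
        raise ValueError("buffer distance must be >= 0")
    geom = lease.polygon.buffer(dist) if dist > 0 else lease.polygon
    ids = _pixels_touching(geom, config)
    if ids.size == 0:
        warnings.warn(f"lease {lease.lease_id}: buffered polygon misses the grid")
    return ids


def control_pool(leases: LeaseSet, config: LandscapeConfig,
                 buffer_distance: float | None = None, pool: str = "lel") -> np.ndarray:
    """Candidate-control pixels.

    ``pool='lel'`` (the main design): exploration-lease polygons minus every
    mining lease with its buffer and minus small-scale leases buffered 5 km.
    ``pool='anywhere'``: the whole extent minus the same exclusions — the
    sensitivity variant where controls need not sit in an exploration lease.
    """
    dist = config.buffer_distance if buffer_distance is None else buffer_distance
    if pool == "lel":
        base = unary_union([l.polygon for l in leases.of_type(LEL)])
    elif pool == "anywhere":
        base = box(0, 0, config.width, config.height)
    else:
        raise ValueError(f"unknown pool '{pool}'")
    exclusions = [l.polygon.buffer(dist) for l in leases.of_type(LML)]
    exclusions += [l.polygon.buffer(SSL_BUFFER) for l in leases.of_type(SSL)]
    if exclusions:
        excl = unary_union(exclusions)
        geom = base.difference(excl)
        # a boundary pixel square can touch both the clipped remainder and
        # the exclusion zone; treated status wins, so drop it here too
        ids = np.setdiff1d(_pixels_touching(geom, config), _pixels_touching(excl, config))
    else:
        ids = _pixels_touching(base, config)
    if ids.size == 0:
        warnings.warn("control pool is empty")
    return ids


def systematic_subsample(pixel_ids: np.ndarray, n_cols: int, factor: int = 4,
                         scheme: str = "one_per_tile") -> np.ndarray:
    """Regular-lattice thinning anchored at the raster origin.

    ``one_per_tile`` keeps the corner pixel of every ``factor x factor``
    tile (one in 16 for the default factor, guaranteeing >= 4 km spacing and
    no direct neighbours); ``quarter`` keeps one pixel per 2x2 tile (25%
    retention). Idempotent and deterministic.
    """
    pixel_ids = np.asarray(pixel_ids)
    rows, cols = pixel_ids // n_cols, pixel_ids % n_cols
    if scheme == "one_per_tile":
        keep = (rows % factor == 0) & (cols % factor == factor - 1)
    elif scheme == "quarter":
        keep = (rows % 2 == 0) & (cols % 2 == 1)
    else:
        raise ValueError(f"unknown subsample scheme '{scheme}'")
    return pixel_ids[keep]


def _majority_region(regions: pd.Series) -> str:
    counts = regions.value_counts()
    top = counts.max()
    # deterministic tie-break: lexicographically first among the most common
    return sorted(counts[counts == top].index)[0]


def assemble_frame(mine: Lease, treated_ids, control_ids, metric: pd.DataFrame,
                   covariates: pd.DataFrame, config: LandscapeConfig,
                   region_merges: dict | None = None,
                   forest_threshold: float = FOREST_COVER_THRESHOLD,
                   min_years: int = 3, horizon: int = 5) -> pd.DataFrame:
    """Assemble one mine's treated/control pixel table.

    Outcome columns ``loss_Y1..loss_Yk`` hold canopy loss (m^2) for years
    ``active_from .. active_from + k - 1`` with ``k = min(horizon,
    years remaining)``; a mine activating too late for ``min_years`` of
    follow-up is rejected. ``pre_loss`` flags any canopy loss in the two
    years before activation. Rows are restricted to forested pixels
    (mean tree cover >= 10%) in the region holding the majority of the
    treated pixels (after any configured region merges).
    """
    if mine.active_from is None:
        raise ValueError("mine is never active")
    t0 = mine.active_from
    n_out = min(horizon, config.n_years - t0 + 1)
    if n_out < min_years:
        raise StudyDesignError(
            f"mine {mine.lease_id}: only {n_out} outcome years available "
            f"(activation year {t0} of {config.n_years})"
        )
    treated_ids = np.unique(np.asarray(treated_ids))
    control_ids = np.setdiff1d(np.unique(np.asarray(control_ids)), treated_ids)

    base = metric.merge(covariates.drop(columns=["x", "y"]), on="pixel_id")
    frame = base[base.pixel_id.isin(np.concatenate([treated_ids, control_ids]))].copy()
    frame["treated"] = frame.pixel_id.isin(treated_ids).astype(int)
    frame["mine_id"] = mine.lease_id
    frame["active_from"] = t0

    frame = frame[frame["forest"] & (frame["mean_treecover"] >= forest_threshold)]
    if (frame["treated"] == 1).sum() == 0:
        raise StudyDesignError(f"mine {mine.lease_id}: no treated pixels survive the forest filter")

    merges = region_merges or {}
    frame["region"] = frame["region"].map(lambda r: merges.get(r, r))
    keep_region = _majority_region(frame.loc[frame.treated == 1, "region"])
    frame = frame[frame["region"] == keep_region]
    if frame["treated"].nunique() < 2:
        raise StudyDesignError(
            f"mine {mine.lease_id}: no controls left in region {keep_region}"
        )

    pre_years = [t for t in (t0 - 1, t0 - 2) if t >= 1]
    if pre_years:
        pre = frame[[f"canopy_loss_Y{t}" for t in pre_years]].sum(axis=1)
        frame["pre_loss"] = (pre > 0).astype(int)
    else:
        frame["pre_loss"] = 0

    for k in range(1, n_out + 1):
        frame[f"loss_Y{k}"] = frame[f"canopy_loss_Y{t0 + k - 1}"]

    cols = (
        ["pixel_id", "x", "y", "treated", "mine_id", "active_from", "region"]
        + CONFOUNDERS
        + [f"loss_Y{k}" for k in range(1, n_out + 1)]
    )
    out = frame[cols].reset_index(drop=True)
    assert not out.pixel_id.duplicated().any()
    return out
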