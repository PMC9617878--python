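"""On-disk interchange: TIFF rasters with a JSON georeferencing sidecar,
GeoJSON lease polygons, CSV tables.

The grids are CRS-free planar metres, so georeferencing reduces to an
origin and a cell size; those travel in ``meta.json`` next to the TIFFs.
Integer rasters round-trip bit-identically.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from shapely.geometry import mapping, shape

from .grids import FineRasterStack
from .landscape import Covariates, LandscapeConfig, Lease, LeaseSet, pixel_covariate_table

__all__ = ["write_landscape", "read_landscape", "write_leases", "read_leases"]


def write_leases(leases: LeaseSet, path):
    features = []
    for lease in leases:
        features.append(
            {
                "type": "Feature",
                "geometry": mapping(lease.polygon),
                "properties": {
                    "id": lease.lease_id,
                    "lease_type": lease.lease_type,
                    "active_from": lease.active_from if lease.active_from is not None else "never",
                    "region": lease.region,
                },
            }
        )
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": features})
    )


def read_leases(path) -> LeaseSet:
    data = json.loads(Path(path).read_text())
    leases = []
    for feat in data["features"]:
        props = feat["properties"]
        active = props["active_from"]
        leases.append(
            Lease(
                lease_id=props["id"],
                lease_type=props["lease_type"],
                polygon=shape(feat["geometry"]),
                active_from=None if active == "never" else int(active),
                region=props.get("region", ""),
            )
        )
    return LeaseSet(leases)


def write_landscape(stack: FineRasterStack, leases: LeaseSet,
                    covariates: Covariates, config: LandscapeConfig, path):
    """Write rasters (TIFF), leases (GeoJSON) and the pixel covariate CSV."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path / "treecover2000.tif", stack.treecover2000.astype(np.float32))
    tifffile.imwrite(path / "lossyear.tif", stack.lossyear.astype(np.int16))
    meta = {
        "origin": list(stack.origin),
        "cell_size": stack.cell_size,
        "n_years": config.n_years,
        "pixel_size": config.pixel_size,
        "block_edge_cells": config.block_edge_cells,
        "buffer_distance": config.buffer_distance,
    }
    (path / "meta.json").write_text(json.dumps(meta, indent=1))
    write_leases(leases, path / "leases.geojson")
    pixel_covariate_table(config, covariates).to_csv(path / "covariates.csv", index=False)


def read_landscape(path):
    """Return (stack, leases, pixel covariate table, meta dict)."""
    path = Path(path)
    meta = json.loads((path / "meta.json").read_text())
    stack = FineRasterStack(
        treecover2000=np.asarray(tifffile.imread(path / "treecover2000.tif"), dtype=float),
        lossyear=np.asarray(tifffile.imread(path / "lossyear.tif")),
        cell_size=float(meta["cell_size"]),
        origin=tuple(meta["origin"]),
    )
    leases = read_leases(path / "leases.geojson")
    table = pd.read_csv(path / "covariates.csv")
    return stack, leases, table, meta
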