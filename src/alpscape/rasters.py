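"""Raster I/O and grid-geometry helpers.

All grids live on a local metric coordinate system with origin at the
top-left corner, row-major storage and cell registration by upper-left
corner. Two grains are used throughout: 25 m (land use) and 100 m
(climate, elevation, substrate, solar), with every 100 m cell containing
exactly a 4x4 block of 25 m cells.

Rasters are written as plain single- or multi-band TIFF files with a JSON
sidecar (``<file>.json``) holding the grid geometry, so artifacts remain
text-inspectable and dependency-light.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import tifffile

BLOCK = 4  # 25 m cells per 100 m cell, per axis
CELL_AREA_HA = 0.0625  # area of a 25 m cell in hectares


@dataclass(frozen=True)
class GridGeometry:
    """Shape of the paired 25 m / 100 m grids.

    ``rows`` and ``cols`` refer to the 25 m grid and must be multiples of 4.
    """

    rows: int
    cols: int
    cell_size: float = 25.0
    origin_x: float = 0.0
    origin_y: float = 0.0

    def __post_init__(self) -> None:
        if self.rows <= 0 or self.cols <= 0:
            raise ValueError("grid dimensions must be positive")
        if self.rows % BLOCK or self.cols % BLOCK:
            raise ValueError("25 m grid dimensions must be multiples of 4")

    @property
    def coarse_shape(self) -> tuple[int, int]:
        return self.rows // BLOCK, self.cols // BLOCK

    @property
    def fine_shape(self) -> tuple[int, int]:
        return self.rows, self.cols


def broadcast_to_fine(coarse: np.ndarray) -> np.ndarray:
    """Broadcast a 100 m field to the 25 m grid (constant within blocks)."""
    return np.repeat(np.repeat(coarse, BLOCK, axis=-2), BLOCK, axis=-1)


def aggregate_to_coarse(fine: np.ndarray, how: str = "mean") -> np.ndarray:
    """Aggregate a 25 m field to 100 m cells by block mean (or majority)."""
    r, c = fine.shape[-2] // BLOCK, fine.shape[-1] // BLOCK
    blocks = fine.reshape(*fine.shape[:-2], r, BLOCK, c, BLOCK)
    if how == "mean":
        return blocks.mean(axis=(-3, -1))
    if how == "majority":
        flat = blocks.swapaxes(-3, -2).reshape(*fine.shape[:-2], r, c, BLOCK * BLOCK)
        out = np.empty(flat.shape[:-1], dtype=fine.dtype)
        for idx in np.ndindex(out.shape):
            vals, counts = np.unique(flat[idx], return_counts=True)
            out[idx] = vals[np.argmax(counts)]
        return out
    raise ValueError(f"unknown aggregation {how!r}")


def parent_coarse_index(geom: GridGeometry) -> np.ndarray:
    """Flat 100 m cell index of every 25 m cell (shape rows x cols)."""
    rr, cc = np.meshgrid(
        np.arange(geom.rows) // BLOCK, np.arange(geom.cols) // BLOCK, indexing="ij"
    )
    return rr * geom.coarse_shape[1] + cc


def write_raster(path: str | Path, array: np.ndarray, geom: GridGeometry | None = None,
                 description: str = "") -> None:
    """Write a raster as TIFF (bands = leading axis for 3-D input)."""
    path = Path(path)
    arr = np.asarray(array)
    if arr.dtype == np.int64:
        arr = arr.astype(np.int32)
    elif arr.dtype == np.float64:
        arr = arr.astype(np.float32)
    tifffile.imwrite(path, arr, description=description)
    if geom is not None:
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(asdict(geom)))


def read_raster(path: str | Path) -> tuple[np.ndarray, GridGeometry | None]:
    path = Path(path)
    arr = tifffile.imread(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    geom = GridGeometry(**json.loads(sidecar.read_text())) if sidecar.exists() else None
    return arr, geom
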