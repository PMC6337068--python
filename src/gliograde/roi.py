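"""Density-based ROI selection: tile a slide image and keep the k most
nucleus-dense tiles.

Tiles are fixed-size and non-overlapping (partial edge tiles are dropped), so
the raw nucleus count per tile ranks tiles identically to density.  Default
tile size for real slides is 5120 px; the synthetic desk scale uses 512 px.
Default k is 5.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from gliograde.segmentation import SegmentationParams, segment_nuclei

logger = logging.getLogger(__name__)

#: real-slide tile resolution
REAL_SLIDE_TILE_SIZE_PX = 5120
#: synthetic desk-scale tile resolution
SYNTHETIC_TILE_SIZE_PX = 512
#: number of highest-density tiles kept as ROIs
DEFAULT_ROI_K = 5


@dataclass(frozen=True)
class TileGrid:
    """Row-major, 0-based tile grid over an image; pixel (0,0) is top-left."""

    tile_size_px: int
    n_rows: int
    n_cols: int

    @property
    def n_tiles(self) -> int:
        return self.n_rows * self.n_cols

    def bounds(self, row: int, col: int) -> tuple[int, int, int, int]:
        """Half-open pixel box (y0, x0, y1, x1) of one tile."""
        t = self.tile_size_px
        return row * t, col * t, (row + 1) * t, (col + 1) * t


@dataclass
class ROISet:
    """Top-k tiles ranked by nucleus count (descending; ties row-major)."""

    entries: list[dict] = field(default_factory=list)  # {row, col, nucleus_count, density_per_px2}
    k: int = DEFAULT_ROI_K

    def __len__(self) -> int:
        return len(self.entries)

    def coords(self) -> list[tuple[int, int]]:
        return [(e["row"], e["col"]) for e in self.entries]


def partition_tiles(image: np.ndarray, tile_size_px: int) -> TileGrid:
    """Partition an image into non-overlapping tiles; partial tiles dropped."""
    if tile_size_px < 64:
        raise ValueError("tile_size_px must be >= 64")
    img = np.asarray(image)
    if img.ndim < 2 or img.shape[0] == 0 or img.shape[1] == 0:
        raise ValueError("image is empty")
    h, w = img.shape[:2]
    n_rows, n_cols = h // tile_size_px, w // tile_size_px
    if n_rows == 0 or n_cols == 0:
        raise ValueError(
            f"image of size {h}x{w} px is smaller than one {tile_size_px}x{tile_size_px} tile"
        )
    return TileGrid(tile_size_px, n_rows, n_cols)


def tile_view(image: np.ndarray, grid: TileGrid, row: int, col: int) -> np.ndarray:
    """Zero-copy view of one tile."""
    y0, x0, y1, x1 = grid.bounds(row, col)
    return image[y0:y1, x0:x1]


def count_nuclei_per_tile(grid: TileGrid, image: np.ndarray,
                          seg_params: SegmentationParams | None = None) -> np.ndarray:
    """Nucleus count per tile via watershed detection; shape (n_rows, n_cols)."""
    counts = np.zeros((grid.n_rows, grid.n_cols), dtype=np.int64)
    for r in range(grid.n_rows):
        for c in range(grid.n_cols):
            try:
                _, records = segment_nuclei(tile_view(image, grid, r, c), seg_params)
            except Exception as exc:  # attach tile coordinates to failures
                raise RuntimeError(f"segmentation failed on tile ({r}, {c}): {exc}") from exc
            counts[r, c] = len(records)
    return counts


def select_rois(counts: np.ndarray, k: int = DEFAULT_ROI_K,
                tile_size_px: int | None = None) -> ROISet:
    """Select the k highest-count tiles; ties broken by (row, col) ascending."""
    if k < 1:
        raise ValueError("k must be >= 1")
    counts = np.asarray(counts)
    n_rows, n_cols = counts.shape
    n_tiles = n_rows * n_cols
    if k > n_tiles:
        logger.warning("k=%d exceeds the %d available tiles; selecting all", k, n_tiles)
    order = sorted(
        ((r, c) for r in range(n_rows) for c in range(n_cols)),
        key=lambda rc: (-int(counts[rc]), rc[0], rc[1]),
    )
    area = float(tile_size_px**2) if tile_size_px else None
    entries = [
        {
            "row": r,
            "col": c,
            "nucleus_count": int(counts[r, c]),
            "density_per_px2": (int(counts[r, c]) / area) if area else None,
        }
        for r, c in order[: min(k, n_tiles)]
    ]
    return ROISet(entries=entries, k=k)
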