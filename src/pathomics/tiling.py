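"""Fixed-size tiling of large RGB images and the tissue-content filter.

Whole-slide exports are split into non-overlapping square tiles on a
row-major grid; partial border strips are discarded.  A tile is kept for
analysis only if at least ``min_fraction`` (default 50%) of its pixels look
like tissue.  "Tissue" is decided per pixel by a whitespace rule: HSV
saturation above 0.05 OR grayscale intensity below 220/255 — stained tissue
is either colorful or dark, blank glass is neither.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from skimage.color import rgb2gray, rgb2hsv

SATURATION_THRESHOLD = 0.05
GRAY_THRESHOLD = 220.0 / 255.0


@dataclass
class RgbTile:
    """One square RGB tile with its grid position and parent case."""

    pixels: np.ndarray  # H x W x 3, uint8
    grid_row: int = 0
    grid_col: int = 0
    case_id: str = ""

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("tile pixels must be H x W x 3")

    @property
    def size(self) -> int:
        return self.pixels.shape[0]


def tile_image(image: np.ndarray, tile_size: int, case_id: str = "") -> list[RgbTile]:
    """Split an RGB image into non-overlapping ``tile_size`` squares.

    The grid covers ``floor(H/s) x floor(W/s)`` tiles; border strips that do
    not fill a tile are dropped.  An image smaller than one tile yields an
    empty list with a warning.
    """
    image = np.asarray(image)
    h, w = image.shape[:2]
    s = int(tile_size)
    if h < s or w < s:
        warnings.warn(f"image {h}x{w} smaller than tile size {s}; no tiles produced",
                      stacklevel=2)
        return []
    tiles = []
    for r in range(h // s):
        for c in range(w // s):
            tiles.append(RgbTile(pixels=image[r * s:(r + 1) * s, c * s:(c + 1) * s],
                                 grid_row=r, grid_col=c, case_id=case_id))
    return tiles


def tissue_mask(pixels: np.ndarray) -> np.ndarray:
    """Boolean per-pixel tissue classification (saturation OR darkness rule)."""
    rgb = np.asarray(pixels, dtype=float) / 255.0
    sat = rgb2hsv(rgb)[..., 1]
    gray = rgb2gray(rgb)
    return (sat > SATURATION_THRESHOLD) | (gray < GRAY_THRESHOLD)


def tissue_fraction(tile: RgbTile) -> float:
    """Fraction of the tile's pixels classified as tissue, in [0, 1]."""
    return float(tissue_mask(tile.pixels).mean())


def filter_tiles(tiles: list[RgbTile], min_fraction: float = 0.5,
                 fractions: list[float] | None = None) -> list[RgbTile]:
    """Keep tiles whose tissue fraction is >= ``min_fraction`` (inclusive).

    Order is preserved.  Pre-computed ``fractions`` may be supplied to avoid
    recomputation.
    """
    if fractions is None:
        fractions = [tissue_fraction(t) for t in tiles]
    return [t for t, f in zip(tiles, fractions) if f >= min_fraction]


def tile_manifest(tiles: list[RgbTile], min_fraction: float = 0.5) -> pd.DataFrame:
    """Per-tile manifest (case_id, grid position, tissue fraction, kept flag)."""
    rows = []
    for t in tiles:
        f = tissue_fraction(t)
        rows.append({"case_id": t.case_id, "grid_row": t.grid_row,
                     "grid_col": t.grid_col, "tissue_fraction": f,
                     "kept": f >= min_fraction})
    return pd.DataFrame(rows, columns=["case_id", "grid_row", "grid_col",
                                       "tissue_fraction", "kept"])


def read_image(path: str | Path) -> np.ndarray:
    """Read a TIFF/PNG RGB image as a uint8 array."""
    import imageio.v3 as iio

    arr = iio.imread(Path(path))
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    return arr[..., :3]


def write_image(path: str | Path, pixels: np.ndarray) -> None:
    import imageio.v3 as iio

    iio.imwrite(Path(path), np.asarray(pixels, dtype=np.uint8))
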