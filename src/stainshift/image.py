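"""The 8-bit RGB tile container and PNG/TIFF round-trip I/O.

Tiles are small fixed-size crops sampled from whole-slide images; here they
are the atomic unit every transform (stain normalization, augmentation,
artifact injection) consumes and produces.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image


class ShapeError(ValueError):
    """Raised when pixel data is not an H x W x 3 8-bit raster."""


@dataclass
class RGBTile:
    """An 8-bit RGB raster with physical pixel-size metadata.

    Parameters
    ----------
    pixels
        ``(H, W, 3)`` array of integer intensities in ``[0, 255]``.
        Any integer dtype is accepted and stored as ``uint8``.
    microns_per_pixel
        Physical resolution of the tile. Metadata only; no operation in
        this package resamples based on it.
    """

    pixels: np.ndarray
    microns_per_pixel: float = 1.0

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ShapeError(f"expected (H, W, 3) RGB pixels, got shape {px.shape}")
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ShapeError(f"empty tile of shape {px.shape}")
        if not np.issubdtype(px.dtype, np.integer):
            if not np.issubdtype(px.dtype, np.floating):
                raise ShapeError(f"pixels must be numeric, got dtype {px.dtype}")
            px = np.rint(px)
        if px.min() < 0 or px.max() > 255:
            raise ShapeError("pixel intensities must lie in [0, 255]")
        if not self.microns_per_pixel > 0:
            raise ValueError("microns_per_pixel must be positive")
        self.pixels = px.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.pixels.shape

    def copy(self) -> "RGBTile":
        return RGBTile(self.pixels.copy(), self.microns_per_pixel)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RGBTile):
            return NotImplemented
        return (
            self.pixels.shape == other.pixels.shape
            and bool(np.all(self.pixels == other.pixels))
            and self.microns_per_pixel == other.microns_per_pixel
        )


def read_tile(path: str | Path, microns_per_pixel: float = 1.0) -> RGBTile:
    """Read a PNG/TIFF/JPEG image as an RGB tile (converting mode if needed)."""
    with Image.open(path) as img:
        arr = np.asarray(img.convert("RGB"))
    return RGBTile(arr, microns_per_pixel)


def write_tile(tile: RGBTile, path: str | Path) -> None:
    """Write a tile as PNG or TIFF, chosen by file extension."""
    Image.fromarray(tile.pixels, mode="RGB").save(path)
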