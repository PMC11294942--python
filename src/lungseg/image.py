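"""Raster containers and grayscale I/O.

Images are 2-D grids of scalar intensities carried in a :class:`RasterImage`
together with the declared encoding range (0-255, 0-65535, [0,1] or Hounsfield
units).  Label masks are plain integer numpy arrays.  Supported on-disk forms:
8/16-bit grayscale PNG and TIFF, and whitespace-separated numeric text grids.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = ["RasterImage", "ImageFormatError", "load_image", "save_image",
           "load_mask", "save_mask"]


class ImageFormatError(ValueError):
    """Unsupported file format, bit depth or color mode."""


@dataclass(frozen=True)
class RasterImage:
    """A 2-D grayscale image with declared value range."""

    pixels: np.ndarray
    value_range: tuple[float, float] = (0.0, 255.0)

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels, dtype=float)
        if arr.ndim != 2 or arr.shape[0] < 1 or arr.shape[1] < 1:
            raise ValueError(f"pixels must be a non-empty 2-D grid, got shape {arr.shape}")
        lo, hi = self.value_range
        if hi <= lo:
            raise ValueError("value_range must have max > min")
        if arr.min() < lo - 1e-9 or arr.max() > hi + 1e-9:
            raise ValueError(
                f"pixel values [{arr.min()}, {arr.max()}] outside declared range {self.value_range}"
            )
        object.__setattr__(self, "pixels", arr)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def with_pixels(self, pixels, value_range=None) -> "RasterImage":
        return RasterImage(pixels, value_range or self.value_range)


_TEXT_SUFFIXES = {".txt", ".dat", ".grid", ".csv"}


def load_image(path) -> RasterImage:
    """Load an 8/16-bit grayscale PNG/TIFF or a numeric text grid."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image file not found: {path}")
    if path.suffix.lower() in _TEXT_SUFFIXES:
        arr = np.loadtxt(path, delimiter="," if path.suffix.lower() == ".csv" else None)
        arr = np.atleast_2d(arr)
        return RasterImage(arr, (min(arr.min(), 0.0), max(arr.max(), 1.0)))
    import imageio.v3 as iio

    arr = iio.imread(path)
    if arr.ndim != 2:
        raise ImageFormatError(f"{path}: color/multichannel images are not supported")
    if arr.dtype == np.uint8:
        rng = (0.0, 255.0)
    elif arr.dtype == np.uint16:
        rng = (0.0, 65535.0)
    else:
        raise ImageFormatError(f"{path}: unsupported bit depth {arr.dtype}")
    return RasterImage(arr.astype(float), rng)


def save_image(image: RasterImage, path) -> None:
    """Save losslessly: uint8/uint16 rasters for integer-range images, text otherwise."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix.lower() in _TEXT_SUFFIXES:
        np.savetxt(path, image.pixels)
        return
    import imageio.v3 as iio

    hi = image.value_range[1]
    if hi <= 255:
        dtype, maxval = np.uint8, 255
    else:
        dtype, maxval = np.uint16, 65535
    arr = np.clip(np.round(image.pixels), 0, maxval).astype(dtype)
    iio.imwrite(path, arr)


def load_mask(path) -> np.ndarray:
    """Load an integer label mask from PNG/TIFF/text."""
    img = load_image(path)
    return np.round(img.pixels).astype(np.int64)


def save_mask(mask: np.ndarray, path) -> None:
    mask = np.asarray(mask)
    if mask.min() < 0 or mask.max() > 65535:
        raise ImageFormatError("mask labels must fit in uint16")
    rng = (0.0, 255.0) if mask.max() <= 255 else (0.0, 65535.0)
    save_image(RasterImage(mask.astype(float), rng), path)
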