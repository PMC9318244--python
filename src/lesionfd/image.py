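"""8-bit grayscale image container and file I/O.

Every processing step in this package operates on :class:`GrayImage`: a 2-D
grid of 8-bit intensities with an optional physical calibration (millimetres
per pixel). Functions that only need the raw intensities also accept a plain
``numpy`` array; :func:`as_pixels` performs the coercion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image


@dataclass(frozen=True)
class GrayImage:
    """A 2-D grid of 8-bit intensities with optional mm-per-pixel calibration.

    Parameters
    ----------
    pixels
        2-D ``uint8`` array, shape ``(height, width)``.
    mm_per_pixel
        Physical side length of one pixel in millimetres, or ``None`` when
        the image is uncalibrated.
    """

    pixels: np.ndarray
    mm_per_pixel: float | None = field(default=None)

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.size == 0:
            raise ValueError("pixels must be a non-empty 2-D array")
        if px.dtype != np.uint8:
            if px.min() < 0 or px.max() > 255:
                raise ValueError("intensities must lie in [0, 255]")
            px = px.astype(np.uint8)
        object.__setattr__(self, "pixels", px)
        if self.mm_per_pixel is not None and self.mm_per_pixel <= 0:
            raise ValueError("mm_per_pixel must be positive")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


def as_pixels(img: "GrayImage | np.ndarray") -> np.ndarray:
    """Return the 2-D uint8 pixel array behind ``img``."""
    if isinstance(img, GrayImage):
        return img.pixels
    arr = np.asarray(img)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D grayscale array, got shape {arr.shape}")
    return arr


def load_image(path: str | Path, mm_per_pixel: float | None = None) -> GrayImage:
    """Read a PNG/TIFF/JPEG file as an 8-bit grayscale image.

    RGB(A) inputs are converted with Rec. 709 luma weights
    (:func:`lesionfd.segmentation.to_grayscale`); already-gray files are
    passed through untouched.
    """
    from .segmentation import to_grayscale  # local import avoids a cycle

    with Image.open(path) as im:
        if im.mode in ("L",):
            arr = np.asarray(im, dtype=np.uint8)
            return GrayImage(arr, mm_per_pixel)
        if im.mode in ("RGBA", "P", "LA"):
            im = im.convert("RGB")
        if im.mode == "RGB":
            rgb = np.asarray(im, dtype=np.uint8)
            gray = to_grayscale(rgb)
            return GrayImage(gray.pixels, mm_per_pixel)
        raise ValueError(f"unsupported image mode {im.mode!r} in {path}")


def save_image(img: GrayImage | np.ndarray, path: str | Path) -> None:
    """Write an 8-bit grayscale image as PNG (or any format PIL infers)."""
    Image.fromarray(as_pixels(img), mode="L").save(path)


def save_mask(mask: np.ndarray, path: str | Path) -> None:
    """Write a boolean mask as a 1-bit PNG."""
    Image.fromarray(np.asarray(mask, dtype=bool)).save(path)


def load_mask(path: str | Path) -> np.ndarray:
    with Image.open(path) as im:
        return np.asarray(im.convert("L")) > 127
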