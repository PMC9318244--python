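"""Lesion segmentation by divide-blend contrast separation.

The pigmented lesion is much darker than the surrounding skin, so dividing
the grayscale photograph by its own tonal inverse saturates the skin to
white while leaving the lesion dark:

    E(x, y) = I(x, y) * 256 / (M(x, y) + 1)

with ``I`` the lower layer (grayscale photo), ``M`` the upper layer
(inverted photo) and ``E`` truncated and clamped to [0, 255]. With
``M = 255 - I`` this reduces to ``E = 256 I / (256 - I)``, a strictly
increasing tone curve that pushes bright background to 255. Thresholding
the blended image then yields a clean binary lesion mask after removing
small background artifacts and filling enclosed holes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .image import GrayImage, as_pixels

#: Rec. 709 luma weights used for RGB -> grayscale conversion.
LUMA_WEIGHTS = (0.2126, 0.7152, 0.0722)

DEFAULT_WHITE_THRESHOLD = 250
DEFAULT_MIN_COMPONENT_FRACTION = 0.01


class LesionNotFoundError(ValueError):
    """Raised when thresholding the blended image leaves no lesion pixels."""


@dataclass(frozen=True)
class SegmentationConfig:
    """Deterministic replacement for the manual background cleanup.

    white_threshold
        Blended intensities strictly below this value are lesion candidates.
    min_component_fraction
        Connected components smaller than this fraction of the largest one
        are treated as background artifacts (speckles, stray hairs) and
        removed before the largest component is kept.
    """

    white_threshold: int = DEFAULT_WHITE_THRESHOLD
    min_component_fraction: float = DEFAULT_MIN_COMPONENT_FRACTION


def to_grayscale(rgb: np.ndarray) -> GrayImage:
    """Convert an 8-bit RGB image to 8-bit grayscale (Rec. 709 luma).

    Rounds half-up to the nearest integer, so pure red maps to
    ``round(0.2126 * 255) = 54``.
    """
    arr = np.asarray(rgb)
    if arr.ndim != 3 or arr.shape[2] < 3:
        raise ValueError("expected an H x W x 3 RGB array")
    if arr.dtype != np.uint8:
        raise ValueError("expected 8-bit (uint8) RGB input")
    w = np.asarray(LUMA_WEIGHTS)
    luma = arr[..., :3].astype(np.float64) @ w
    return GrayImage(np.floor(luma + 0.5).astype(np.uint8))


def invert(img: GrayImage | np.ndarray) -> GrayImage:
    """Invert tones: each pixel v -> 255 - v (an involution)."""
    return GrayImage(255 - as_pixels(img))


def divide_blend(lower: GrayImage | np.ndarray, upper: GrayImage | np.ndarray) -> GrayImage:
    """Divide blend of two 8-bit layers: E = lower*256 / (upper+1).

    The quotient is truncated toward zero and clamped to [0, 255], matching
    the integer behaviour of raster editors' division blend mode.
    """
    lo = as_pixels(lower).astype(np.int64)
    up = as_pixels(upper).astype(np.int64)
    if lo.shape != up.shape:
        raise ValueError(f"layer dimensions differ: {lo.shape} vs {up.shape}")
    e = (lo * 256) // (up + 1)
    return GrayImage(np.clip(e, 0, 255).astype(np.uint8))


def blend_with_inverse(img: GrayImage | np.ndarray) -> GrayImage:
    """Divide-blend an image with its own tonal inverse (the full recipe)."""
    return divide_blend(img, invert(img))


def extract_mask(
    blended: GrayImage | np.ndarray,
    config: SegmentationConfig | None = None,
) -> np.ndarray:
    """Extract a single-component binary lesion mask from a blended image.

    Pixels strictly below ``white_threshold`` are lesion candidates.
    Components smaller than ``min_component_fraction`` of the largest are
    removed, the largest component is kept, and fully enclosed holes are
    filled — a deterministic stand-in for erasing background artifacts by
    hand.

    Returns
    -------
    numpy.ndarray
        Boolean mask with exactly one connected foreground component.

    Raises
    ------
    LesionNotFoundError
        If no pixel falls below the threshold.
    """
    cfg = config or SegmentationConfig()
    px = as_pixels(blended)
    candidates = px < cfg.white_threshold
    if not candidates.any():
        raise LesionNotFoundError(
            f"no lesion found: no pixel below white_threshold={cfg.white_threshold}"
        )
    # 8-connectivity for the dark foreground
    labels, _ = ndimage.label(candidates, structure=np.ones((3, 3), dtype=int))
    sizes = np.bincount(labels.ravel())[1:]
    # drop artifact components below the size fraction, then keep the largest
    too_small = np.flatnonzero(sizes < cfg.min_component_fraction * sizes.max()) + 1
    if too_small.size:
        labels[np.isin(labels, too_small)] = 0
    largest = int(np.argmax(sizes)) + 1
    mask = labels == largest
    return ndimage.binary_fill_holes(mask)


def segment(
    img: GrayImage | np.ndarray,
    config: SegmentationConfig | None = None,
) -> tuple[GrayImage, np.ndarray]:
    """Full shape-analysis preparation: blend with inverse, then mask.

    Returns the blended image (dark lesion on white background, the input
    to shape fractal analysis) and the binary lesion mask.
    """
    blended = blend_with_inverse(img)
    mask = extract_mask(blended, config)
    return blended, mask
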