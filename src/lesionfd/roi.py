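"""Non-overlapping square ROI extraction inside the lesion mask.

Surface (texture) analysis runs on fixed-size square regions of interest
that lie entirely within the lesion, so the skin background never enters
the texture statistic. Placement is a deterministic greedy raster scan:
candidate origins are visited top-left to bottom-right at stride 1, and a
position is accepted iff its square is fully inside the mask and overlaps
no previously accepted ROI. Larger lesions therefore yield more ROIs, and
the set jointly covers the lesion rather than a hand-picked "typical"
area — deliberate, to avoid selection bias.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .image import GrayImage, as_pixels

#: ROI side used in the study design (the smallest lesion set the size).
DEFAULT_ROI_SIZE = 450


@dataclass(frozen=True)
class ROISet:
    """The accepted ROIs of one lesion image.

    ``origins`` are (row, col) top-left corners in raster order; ``patches``
    the corresponding roi_size × roi_size grayscale crops. ``too_small`` is
    set when no ROI fits, flagging the lesion for exclusion from surface
    analysis.
    """

    roi_size: int
    origins: tuple[tuple[int, int], ...]
    patches: tuple[np.ndarray, ...]

    @property
    def too_small(self) -> bool:
        return len(self.origins) == 0

    def __len__(self) -> int:
        return len(self.origins)


def _valid_origins(mask: np.ndarray, size: int) -> np.ndarray:
    """Boolean grid of origins whose size×size square lies fully in the mask."""
    h, w = mask.shape
    if h < size or w < size:
        return np.zeros((0, 0), dtype=bool)
    integral = np.pad(mask.astype(np.int64).cumsum(0).cumsum(1), ((1, 0), (1, 0)))
    sums = (
        integral[size:, size:]
        - integral[:-size, size:]
        - integral[size:, :-size]
        + integral[:-size, :-size]
    )
    return sums == size * size


def extract_rois(
    img: GrayImage | np.ndarray,
    mask: np.ndarray,
    roi_size: int = DEFAULT_ROI_SIZE,
) -> ROISet:
    """Greedy raster placement of non-overlapping in-lesion square ROIs.

    Equivalent to scanning every stride-1 candidate origin in raster order
    and accepting each position whose square is inside the mask and free of
    previously accepted ROIs; implemented with an integral image and a
    blocked-origin bitmap for speed. Fully deterministic.
    """
    px = as_pixels(img)
    mask = np.asarray(mask, dtype=bool)
    if px.shape != mask.shape:
        raise ValueError("image and mask dimensions differ")
    if roi_size < 1:
        raise ValueError("roi_size must be positive")
    valid = _valid_origins(mask, roi_size)
    origins: list[tuple[int, int]] = []
    if valid.size:
        open_ = valid.copy()  # origins still both valid and non-overlapping
        nrows, ncols = open_.shape
        flat = open_.ravel()
        while True:
            idx = int(np.argmax(flat))
            if not flat[idx]:
                break
            y, x = divmod(idx, ncols)
            origins.append((y, x))
            # any origin within roi_size-1 in both axes would overlap
            y0, x0 = max(0, y - roi_size + 1), max(0, x - roi_size + 1)
            open_[y0 : y + roi_size, x0 : x + roi_size] = False
    patches = tuple(
        px[y : y + roi_size, x : x + roi_size].copy() for y, x in origins
    )
    return ROISet(roi_size=roi_size, origins=tuple(origins), patches=patches)
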