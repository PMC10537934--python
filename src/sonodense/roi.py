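"""Region-of-interest handling for B-mode breast ultrasound images.

The breast tissue between the skin line and the pectoral muscle is the
region of interest (ROI).  Because gray-level features are computed over a
rectangular window, the largest axis-aligned rectangle fully inside the ROI
mask is extracted from every image before histogramming.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
import json

import numpy as np
from numba import njit


class EmptyROIError(ValueError):
    """Raised when a mask contains no tissue pixel (unusable image)."""


@dataclass(frozen=True)
class ROIRect:
    """Axis-aligned rectangle, 0-based, half-open on both axes."""

    top_row: int
    left_col: int
    height: int
    width: int

    def __post_init__(self) -> None:
        if self.height < 1 or self.width < 1:
            raise ValueError("rectangle must have height >= 1 and width >= 1")

    @property
    def area(self) -> int:
        return self.height * self.width

    @property
    def bottom_row(self) -> int:
        """One past the last row (half-open)."""
        return self.top_row + self.height

    @property
    def right_col(self) -> int:
        """One past the last column (half-open)."""
        return self.left_col + self.width

    def to_json(self) -> str:
        return json.dumps({"top": self.top_row, "left": self.left_col,
                           "height": self.height, "width": self.width})

    @classmethod
    def from_json(cls, s: str) -> "ROIRect":
        d = json.loads(s)
        return cls(d["top"], d["left"], d["height"], d["width"])


def band_mask(image_shape: tuple[int, int], skin_row: int, muscle_row: int) -> np.ndarray:
    """Boolean mask of the tissue band strictly between skin and muscle.

    Rows ``skin_row`` and ``muscle_row`` themselves are excluded: they mark
    the skin line and the top of the pectoral muscle, not breast tissue.

    Parameters
    ----------
    image_shape : (rows, cols)
    skin_row, muscle_row : int
        Must satisfy ``0 <= skin_row < muscle_row <= rows``.
    """
    rows, cols = image_shape
    if not (0 <= skin_row < muscle_row <= rows):
        raise ValueError(
            f"need 0 <= skin_row < muscle_row <= {rows}, "
            f"got skin_row={skin_row}, muscle_row={muscle_row}"
        )
    mask = np.zeros((rows, cols), dtype=bool)
    mask[skin_row + 1:muscle_row, :] = True
    return mask


@njit(cache=True)
def _best_rectangle_kernel(mask: np.ndarray) -> tuple[int, int, int, int]:
    """Monotone-stack scan; returns (top_row, left_col, height, width)."""
    n_rows, n_cols = mask.shape
    heights = np.zeros(n_cols, dtype=np.int64)
    stack = np.empty(n_cols + 1, dtype=np.int64)
    best_area = 0
    best_top = best_left = best_h = best_w = 0
    for r in range(n_rows):
        for c in range(n_cols):
            heights[c] = heights[c] + 1 if mask[r, c] else 0
        top = -1  # stack pointer; stack holds columns with increasing heights
        for c in range(n_cols + 1):
            h = heights[c] if c < n_cols else 0
            while top >= 0 and heights[stack[top]] > h:
                cand_h = heights[stack[top]]
                top -= 1
                left = stack[top] + 1 if top >= 0 else 0
                cand_w = c - left
                area = cand_h * cand_w
                cand_top = r - cand_h + 1
                if area > 0:
                    better = area > best_area
                    if not better and area == best_area:
                        if cand_top < best_top:
                            better = True
                        elif cand_top == best_top:
                            if left < best_left:
                                better = True
                            elif left == best_left and cand_h > best_h:
                                better = True
                    if better:
                        best_area = area
                        best_top, best_left = cand_top, left
                        best_h, best_w = cand_h, cand_w
            top += 1
            stack[top] = c
    return best_top, best_left, best_h, best_w


def largest_rectangle(mask: np.ndarray) -> ROIRect:
    """Largest axis-aligned all-true rectangle in a boolean mask.

    Row-stacked histogram method: for every row, the run of consecutive
    true pixels ending at that row forms a histogram whose largest
    rectangle is found with a monotone stack; overall O(rows * cols).

    Ties on area are broken deterministically: smallest ``top_row``, then
    smallest ``left_col``, then largest ``height``.
    """
    mask = np.ascontiguousarray(mask, dtype=bool)
    if mask.ndim != 2:
        raise ValueError("mask must be 2-D")
    if not mask.any():
        raise EmptyROIError("mask contains no true pixel")
    top, left, h, w = _best_rectangle_kernel(mask)
    return ROIRect(int(top), int(left), int(h), int(w))


def crop(image: np.ndarray, rect: ROIRect) -> np.ndarray:
    """Sub-image covered by ``rect``; pixel values unchanged."""
    image = np.asarray(image)
    rows, cols = image.shape[:2]
    if rect.top_row < 0 or rect.left_col < 0 or rect.bottom_row > rows or rect.right_col > cols:
        raise ValueError(f"rectangle {rect} out of bounds for image shape {image.shape}")
    return image[rect.top_row:rect.bottom_row, rect.left_col:rect.right_col]


def rect_inside_mask(rect: ROIRect, mask: np.ndarray) -> bool:
    """True iff every pixel of ``rect`` is true in ``mask``."""
    sub = mask[rect.top_row:rect.bottom_row, rect.left_col:rect.right_col]
    return sub.shape == (rect.height, rect.width) and bool(sub.all())
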