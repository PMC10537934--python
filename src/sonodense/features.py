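"""Gray-level histogram features.

Each rectangular ROI yields a 256-level gray histogram.  The five per-patient
histograms are pooled by summing counts, giving one combined ROI per breast.
The pooled histogram is reduced to 16 equal-width gray-level bins ordered
from white (bin 1, GLVs 240-255) to black (bin 16, GLVs 0-15), expressed as
percentages of ROI pixels.  The 16 percentages sum to 100 by construction,
so bins 1-15 carry all the information and serve as the model predictors;
the darkest bin (16) is omitted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .roi import ROIRect

N_BINS = 16
BIN_WIDTH = 256 // N_BINS  # 16 consecutive gray levels per bin
N_PREDICTORS = N_BINS - 1
PREDICTOR_COLUMNS = [f"bin_{b:02d}" for b in range(1, N_PREDICTORS + 1)]
ALL_BIN_COLUMNS = [f"bin_{b:02d}" for b in range(1, N_BINS + 1)]


def bin_glv_range(b: int) -> tuple[int, int]:
    """Inclusive GLV range [lo, hi] covered by white-ordered bin ``b`` (1-16)."""
    if not 1 <= b <= N_BINS:
        raise ValueError(f"bin index must be in 1..{N_BINS}, got {b}")
    lo = 256 - BIN_WIDTH * b
    return lo, lo + BIN_WIDTH - 1


@dataclass(frozen=True)
class GrayHistogram:
    """Exact pixel counts per gray level value (GLV) 0..255."""

    counts: np.ndarray  # shape (256,), non-negative integers

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.shape != (256,):
            raise ValueError("counts must have shape (256,)")
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "counts", counts)

    @property
    def total_pixels(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class BinFeatures:
    """16 gray-level bin percentages, white (bin 1) to black (bin 16)."""

    bins: np.ndarray  # shape (16,), percentages summing to 100

    def __post_init__(self) -> None:
        bins = np.asarray(self.bins, dtype=float)
        if bins.shape != (N_BINS,):
            raise ValueError(f"bins must have shape ({N_BINS},)")
        object.__setattr__(self, "bins", bins)

    @property
    def predictors(self) -> np.ndarray:
        """Bins 1..15 — the model predictors (darkest bin omitted)."""
        return self.bins[:N_PREDICTORS]


def histogram(image: np.ndarray, rect: ROIRect) -> GrayHistogram:
    """Gray-level histogram of the pixels inside ``rect``."""
    image = np.asarray(image)
    sub = image[rect.top_row:rect.bottom_row, rect.left_col:rect.right_col]
    if sub.shape != (rect.height, rect.width):
        raise ValueError(f"rectangle {rect} out of bounds for image shape {image.shape}")
    if sub.size == 0:
        raise ValueError("zero-area rectangle")
    if sub.min() < 0 or sub.max() > 255:
        raise ValueError("image values must be 8-bit gray levels in 0..255")
    counts = np.bincount(sub.astype(np.int64).ravel(), minlength=256)
    return GrayHistogram(counts)


def pool(histograms: list[GrayHistogram]) -> GrayHistogram:
    """Combine per-image histograms by summing counts (one combined ROI)."""
    if not histograms:
        raise ValueError("cannot pool an empty list of histograms")
    total = np.zeros(256, dtype=np.int64)
    for h in histograms:
        total += h.counts
    return GrayHistogram(total)


def bin_features(hist: GrayHistogram) -> BinFeatures:
    """Reduce a 256-level histogram to 16 white-to-black bin percentages."""
    if hist.total_pixels == 0:
        raise ValueError("empty histogram: no pixels to bin")
    # counts reshaped to (16, 16): row g covers GLVs [16g, 16g+15], dark first
    by_glv_block = hist.counts.reshape(N_BINS, BIN_WIDTH).sum(axis=1)
    # white-ordered: bin 1 = brightest block, bin 16 = darkest
    bins = 100.0 * by_glv_block[::-1] / hist.total_pixels
    return BinFeatures(bins)


def feature_table(
    per_patient_hists: dict[str, list[GrayHistogram]],
    pmd_observed: dict[str, float],
) -> pd.DataFrame:
    """Pool each patient's histograms and tabulate bin features.

    Returns a DataFrame with columns ``patient_id, bin_01..bin_16,
    pmd_observed``; models consume ``bin_01..bin_15``.
    """
    rows = []
    for pid, hists in per_patient_hists.items():
        feats = bin_features(pool(hists))
        row = {"patient_id": pid}
        row.update({col: feats.bins[i] for i, col in enumerate(ALL_BIN_COLUMNS)})
        row["pmd_observed"] = pmd_observed[pid]
        rows.append(row)
    return pd.DataFrame(rows, columns=["patient_id", *ALL_BIN_COLUMNS, "pmd_observed"])
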