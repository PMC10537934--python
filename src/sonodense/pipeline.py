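"""End-to-end plumbing: images -> rectangles -> histograms -> feature table.

Shared by the command-line interface, the test suite and analysis scripts.
Feature extraction accepts either a manifest of image/mask files on disk or
an in-memory cohort from the synthetic generator, so real annotated images
can be substituted for synthetic ones without touching the rest of the
pipeline.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from . import features as feat
from . import roi
from .syndata import GeneratorConfig, iter_cohort


def patient_features_from_arrays(images: list[np.ndarray],
                                 masks: list[np.ndarray]) -> feat.BinFeatures:
    """Pool the largest-rectangle histograms of one patient's images."""
    hists = []
    for img, msk in zip(images, masks):
        rect = roi.largest_rectangle(np.asarray(msk, dtype=bool))
        hists.append(feat.histogram(img, rect))
    return feat.bin_features(feat.pool(hists))


def cohort_feature_table(config: GeneratorConfig) -> tuple[pd.DataFrame, list]:
    """Generate a synthetic cohort in memory and compute its feature table.

    Returns (table, truths); the table has columns ``patient_id,
    bin_01..bin_16, pmd_observed``.
    """
    rows, truths = [], []
    for truth, images, masks in iter_cohort(config):
        truths.append(truth)
        f = patient_features_from_arrays(images, masks)
        row = {"patient_id": truth.patient_id}
        row.update({col: f.bins[i] for i, col in enumerate(feat.ALL_BIN_COLUMNS)})
        row["pmd_observed"] = truth.pmd_observed
        rows.append(row)
    cols = ["patient_id", *feat.ALL_BIN_COLUMNS, "pmd_observed"]
    return pd.DataFrame(rows, columns=cols), truths


def features_from_manifest(manifest: pd.DataFrame, base_dir) -> pd.DataFrame:
    """Compute the per-patient feature table from images on disk.

    The manifest has one row per image with columns ``patient_id, view,
    image, mask, pmd_observed`` (paths relative to ``base_dir``); each
    mask is a 0/255 PNG from which the largest all-true rectangle is taken.
    """
    base = Path(base_dir)
    rows = []
    for pid, grp in manifest.groupby("patient_id", sort=True):
        hists = []
        for _, r in grp.sort_values("view").iterrows():
            img = np.asarray(iio.imread(base / r["image"]))
            msk = np.asarray(iio.imread(base / r["mask"])) > 127
            rect = roi.largest_rectangle(msk)
            hists.append(feat.histogram(img, rect))
        f = feat.bin_features(feat.pool(hists))
        pmd_vals = grp["pmd_observed"].unique()
        if len(pmd_vals) != 1:
            raise ValueError(f"inconsistent pmd_observed for patient {pid}")
        row = {"patient_id": pid}
        row.update({col: f.bins[i] for i, col in enumerate(feat.ALL_BIN_COLUMNS)})
        row["pmd_observed"] = float(pmd_vals[0])
        rows.append(row)
    cols = ["patient_id", *feat.ALL_BIN_COLUMNS, "pmd_observed"]
    return pd.DataFrame(rows, columns=cols)
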