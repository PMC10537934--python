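"""Synthetic breast-ultrasound cohort generator.

Emulates the study design this package analyses: each patient has a latent
breast density (a fraction), a percentage-mammographic-density (PMD) outcome
obtained by averaging two noisy readers, and five B-mode-like gray-scale
images (one retro-mamillary view plus one per quadrant).  Every image shows
a bright skin band at the top, a dark pectoral-muscle band at the bottom,
and in between a speckled two-tissue field in which the fraction of bright
(fibroglandular-like) pixels is tied to the latent density through a
``signal_strength`` knob.  All outputs are pure functions of the seed, and
full ground truth is returned so recovery tests can compare against it.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy import ndimage

from . import roi

MANIFEST_COLUMNS = ["patient_id", "view", "image", "mask", "pmd_observed"]
VIEWS_PER_PATIENT = 5


class ConfigurationError(ValueError):
    """Raised when generator settings violate an invariant."""


@dataclass(frozen=True)
class GeneratorConfig:
    """Settings of the synthetic cohort.

    Defaults reproduce the emulated study conditions: 168 patients, five
    400x400 images each, a PMD distribution with mean 0.422 and variance
    0.0396 on the fraction scale, and two readers with 0.03 noise.
    """

    n_patients: int = 168
    image_height: int = 400
    image_width: int = 400
    pmd_mean: float = 0.422
    pmd_var: float = 0.0396
    reader_sd: float = 0.03
    #: 1 = bright-pixel fraction fully determined by latent density, 0 = unrelated
    signal_strength: float = 0.2
    #: sd of the per-view perturbation of the bright-tissue fraction
    view_sd: float = 0.12
    #: gamma shape of the multiplicative speckle (variance 1/shape)
    speckle_shape: float = 4.0
    fibro_gray: float = 170.0
    fat_gray: float = 80.0
    skin_gray: float = 220.0
    muscle_gray: float = 40.0
    #: spatial correlation length of the tissue field, pixels
    blob_scale: float = 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 0:
            raise ConfigurationError("n_patients must be >= 0")
        if not 0.0 < self.pmd_mean < 1.0:
            raise ConfigurationError("pmd_mean must lie in (0, 1)")
        if not 0.0 < self.pmd_var < self.pmd_mean * (1.0 - self.pmd_mean):
            raise ConfigurationError(
                "pmd_var must satisfy 0 < pmd_var < pmd_mean*(1-pmd_mean) "
                f"(= {self.pmd_mean * (1 - self.pmd_mean):.4f})"
            )
        if self.reader_sd < 0:
            raise ConfigurationError("reader_sd must be >= 0")
        if not 0.0 <= self.signal_strength <= 1.0:
            raise ConfigurationError("signal_strength must lie in [0, 1]")
        if self.speckle_shape <= 0:
            raise ConfigurationError("speckle_shape must be > 0")
        for name in ("fibro_gray", "fat_gray", "skin_gray", "muscle_gray"):
            v = getattr(self, name)
            if not 0 <= v <= 255:
                raise ConfigurationError(f"{name} must lie in [0, 255]")
        if self.image_height < 10 or self.image_width < 4:
            raise ConfigurationError(
                "image too small to hold skin, tissue and muscle bands"
            )


@dataclass(frozen=True)
class PatientTruth:
    """Ground truth for one synthetic patient."""

    patient_id: str
    latent_density: float
    reader_values: tuple[float, float]
    pmd_observed: float
    bright_fractions: tuple[float, ...]  # target bright-tissue fraction per view
    skin_rows: tuple[int, ...]
    muscle_rows: tuple[int, ...]

    def __post_init__(self) -> None:
        assert abs(self.pmd_observed - float(np.mean(self.reader_values))) < 1e-12
        assert all(s < m for s, m in zip(self.skin_rows, self.muscle_rows))


def beta_moment_match(mean: float, var: float) -> tuple[float, float]:
    """Beta shape parameters (a, b) with the given mean and variance.

    Uses nu = mean*(1-mean)/var - 1, a = mean*nu, b = (1-mean)*nu; valid
    only when 0 < var < mean*(1-mean).
    """
    if not 0.0 < mean < 1.0:
        raise ConfigurationError("mean must lie in (0, 1)")
    if not 0.0 < var < mean * (1.0 - mean):
        raise ConfigurationError(
            f"variance {var} must lie in (0, mean*(1-mean)) = (0, {mean * (1 - mean):.6f})"
        )
    nu = mean * (1.0 - mean) / var - 1.0
    return mean * nu, (1.0 - mean) * nu


def _as_rng(rng_state: np.random.Generator | int) -> np.random.Generator:
    if isinstance(rng_state, np.random.Generator):
        return rng_state
    return np.random.default_rng(rng_state)


def sample_pmd(config: GeneratorConfig, count: int,
               rng_state: np.random.Generator | int) -> np.ndarray:
    """Draw latent densities from the moment-matched Beta prior."""
    if count < 0:
        raise ValueError("count must be >= 0")
    rng = _as_rng(rng_state)
    a, b = beta_moment_match(config.pmd_mean, config.pmd_var)
    return rng.beta(a, b, size=count)


def simulate_readers(d: float, reader_sd: float,
                     rng_state: np.random.Generator | int,
                     ) -> tuple[tuple[float, float], float]:
    """Two independent noisy density readings of ``d`` and their average.

    Each reading is a Gaussian perturbation of ``d`` truncated to [0, 1];
    the averaged value is the PMD outcome used throughout the pipeline.
    """
    if not 0.0 <= d <= 1.0:
        raise ValueError("latent density must lie in [0, 1]")
    if reader_sd < 0:
        raise ValueError("reader_sd must be >= 0")
    rng = _as_rng(rng_state)
    readings = np.clip(d + reader_sd * rng.standard_normal(2), 0.0, 1.0)
    values = (float(readings[0]), float(readings[1]))
    return values, float(np.mean(readings))


def _sample_band_rows(config: GeneratorConfig, rng: np.random.Generator) -> tuple[int, int]:
    h = config.image_height
    skin_lo, skin_hi = max(1, int(0.06 * h)), max(2, int(0.12 * h))
    musc_lo, musc_hi = int(0.78 * h), int(0.90 * h)
    if musc_lo <= skin_hi + 1:
        raise ConfigurationError("image too small to hold skin, tissue and muscle bands")
    skin_row = int(rng.integers(skin_lo, skin_hi + 1))
    muscle_row = int(rng.integers(musc_lo, musc_hi + 1))
    return skin_row, muscle_row


def sample_patient_truth(config: GeneratorConfig, patient_id: str,
                         rng_state: np.random.Generator | int) -> PatientTruth:
    """Latent density, reader outcome and per-view geometry for one patient."""
    rng = _as_rng(rng_state)
    d = float(sample_pmd(config, 1, rng)[0])
    reader_values, pmd_observed = simulate_readers(d, config.reader_sd, rng)
    base_p = config.signal_strength * d + (1.0 - config.signal_strength) * 0.5
    bright = np.clip(base_p + config.view_sd * rng.standard_normal(VIEWS_PER_PATIENT),
                     0.0, 1.0)
    skin_rows, muscle_rows = [], []
    for _ in range(VIEWS_PER_PATIENT):
        s, m = _sample_band_rows(config, rng)
        skin_rows.append(s)
        muscle_rows.append(m)
    return PatientTruth(
        patient_id=patient_id,
        latent_density=d,
        reader_values=reader_values,
        pmd_observed=pmd_observed,
        bright_fractions=tuple(float(p) for p in bright),
        skin_rows=tuple(skin_rows),
        muscle_rows=tuple(muscle_rows),
    )


def generate_image(truth: PatientTruth, view_index: int, config: GeneratorConfig,
                   rng_state: np.random.Generator | int,
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Render one 8-bit view for a patient plus its ROI mask.

    Layout: rows above ``skin_row`` are skin, rows at or below ``muscle_row``
    are muscle, and the band between them is a spatially correlated
    two-tissue field whose bright (fibroglandular-like) pixel fraction
    equals the recorded per-view target.  The whole image is degraded by
    multiplicative gamma speckle with unit mean.  The mask marks exactly
    the rows strictly between ``skin_row`` and ``muscle_row``.
    """
    if not 1 <= view_index <= VIEWS_PER_PATIENT:
        raise ValueError(f"view_index must be in 1..{VIEWS_PER_PATIENT}")
    rng = _as_rng(rng_state)
    h, w = config.image_height, config.image_width
    skin_row = truth.skin_rows[view_index - 1]
    muscle_row = truth.muscle_rows[view_index - 1]
    if not 0 < skin_row < muscle_row < h:
        raise ConfigurationError("band rows do not fit inside the image")

    mean_gray = np.empty((h, w), dtype=float)
    mean_gray[:skin_row, :] = config.skin_gray
    mean_gray[muscle_row:, :] = config.muscle_gray

    # spatially correlated binary tissue field between skin and muscle
    p_bright = truth.bright_fractions[view_index - 1]
    n_tissue_rows = muscle_row - skin_row
    field = rng.standard_normal((n_tissue_rows, w))
    field = ndimage.gaussian_filter(field, sigma=config.blob_scale, mode="reflect")
    # threshold at the empirical quantile so the bright fraction hits its target
    thr = np.quantile(field, 1.0 - p_bright)
    tissue = np.where(field > thr, config.fibro_gray, config.fat_gray)
    mean_gray[skin_row:muscle_row, :] = tissue

    speckle = rng.gamma(shape=config.speckle_shape,
                        scale=1.0 / config.speckle_shape, size=(h, w))
    image = np.clip(np.rint(mean_gray * speckle), 0, 255).astype(np.uint8)
    mask = roi.band_mask((h, w), skin_row, muscle_row)
    return image, mask


def generate_patient(config: GeneratorConfig, patient_id: str,
                     rng_state: np.random.Generator | int,
                     ) -> tuple[PatientTruth, list[np.ndarray], list[np.ndarray]]:
    """Truth plus the five rendered (image, mask) pairs, all in memory."""
    rng = _as_rng(rng_state)
    truth = sample_patient_truth(config, patient_id, rng)
    images, masks = [], []
    for view in range(1, VIEWS_PER_PATIENT + 1):
        img, msk = generate_image(truth, view, config, rng)
        images.append(img)
        masks.append(msk)
    return truth, images, masks


def iter_cohort(config: GeneratorConfig):
    """Yield (truth, images, masks) per patient, reproducibly from the seed.

    Each patient draws from an independent child stream of the config seed,
    so cohorts of different sizes share their leading patients.
    """
    root = np.random.SeedSequence(config.seed)
    children = root.spawn(config.n_patients)
    for i, child in enumerate(children):
        pid = f"P{i + 1:04d}"
        yield generate_patient(config, pid, np.random.default_rng(child))


def generate_cohort(config: GeneratorConfig, out_dir: str | os.PathLike,
                    ) -> tuple[pd.DataFrame, list[PatientTruth]]:
    """Write the full cohort to disk and return (manifest, truths).

    Images and masks are stored as 8-bit single-channel PNGs under
    ``out_dir/images``; the manifest CSV has one row per image with columns
    ``patient_id, view, image, mask, pmd_observed``.
    """
    out_dir = Path(out_dir)
    img_dir = out_dir / "images"
    img_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    truths = []
    for truth, images, masks in iter_cohort(config):
        truths.append(truth)
        for view, (img, msk) in enumerate(zip(images, masks), start=1):
            img_path = img_dir / f"{truth.patient_id}_v{view}.png"
            mask_path = img_dir / f"{truth.patient_id}_v{view}_mask.png"
            iio.imwrite(img_path, img)
            iio.imwrite(mask_path, (msk.astype(np.uint8) * 255))
            rows.append({
                "patient_id": truth.patient_id,
                "view": view,
                "image": str(img_path.relative_to(out_dir)),
                "mask": str(mask_path.relative_to(out_dir)),
                "pmd_observed": truth.pmd_observed,
            })
    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest, truths


def linear_signal_cohort(n: int, oracle_r2: float,
                         rng_state: np.random.Generator | int,
                         n_predictors: int = 15,
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Feature-level cohort with a known linear signal of given oracle R².

    Returns (X, y) where y = X @ beta + noise and the population fraction of
    variance explained by the linear predictor equals ``oracle_r2`` by
    construction.  Used to calibrate model-recovery tests against a known
    generative truth.
    """
    if not 0.0 <= oracle_r2 < 1.0:
        raise ValueError("oracle_r2 must lie in [0, 1)")
    rng = _as_rng(rng_state)
    X = rng.standard_normal((n, n_predictors))
    beta = rng.standard_normal(n_predictors)
    signal = X @ beta
    signal_var = float(beta @ beta)  # population variance of the signal
    if oracle_r2 == 0.0:
        noise_var = 1.0
        signal = np.zeros(n)
    else:
        noise_var = signal_var * (1.0 - oracle_r2) / oracle_r2
    y = signal + np.sqrt(noise_var) * rng.standard_normal(n)
    return X, y
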