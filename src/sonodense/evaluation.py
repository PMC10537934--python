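"""Model evaluation: apparent and cross-validated performance.

The benchmark protocol is repeated k-fold cross-validation (default 100
repeats of 3 folds).  In every repeat the patients are randomly partitioned
into three near-equal folds; each model — including its variable selection
and penalty tuning — is refit on two folds and scored on the held-out fold.
Cross-validated MSE and R² are averages over all repeat × fold records;
apparent measures come from fitting and scoring on the complete data set.
The out-of-sample R² is defined relative to the held-out fold's own
variance and can be negative: a model that predicts worse than the fold
mean scores below zero.  The model with the smallest cross-validated MSE
is flagged as the final model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import models as models_mod
from .features import PREDICTOR_COLUMNS
from .models import FittedModel, ModelSpec

logger = logging.getLogger(__name__)


class UndefinedMetricError(ValueError):
    """Raised when a metric is undefined (e.g. zero-variance observations)."""


def mse(y_obs: np.ndarray, y_pred: np.ndarray) -> float:
    """Mean squared error."""
    y_obs = np.asarray(y_obs, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_obs.shape != y_pred.shape or y_obs.ndim != 1 or len(y_obs) == 0:
        raise ValueError("y_obs and y_pred must be equal-length non-empty 1-D arrays")
    return float(np.mean((y_obs - y_pred) ** 2))


def r_squared(y_obs: np.ndarray, y_pred: np.ndarray) -> float:
    """R² = 1 - MSE / Var(y_obs), with the population-variance divisor n.

    On training data with a least-squares fit this lies in [0, 1]; on
    held-out data it can fall below zero.
    """
    y_obs = np.asarray(y_obs, dtype=float)
    if len(y_obs) < 2:
        raise UndefinedMetricError("R² needs at least 2 observations")
    var = float(np.var(y_obs))
    if var == 0.0:
        raise UndefinedMetricError("R² undefined: observed values have zero variance")
    return 1.0 - mse(y_obs, y_pred) / var


@dataclass(frozen=True)
class CVConfig:
    repeats: int = 100
    folds: int = 3
    seed: int = 0
    #: "fold_local": average per-fold metrics; "pooled": pool out-of-fold
    #: predictions within each repeat before computing metrics
    aggregation: str = "fold_local"

    def __post_init__(self) -> None:
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.aggregation not in ("fold_local", "pooled"):
            raise ValueError("aggregation must be 'fold_local' or 'pooled'")


@dataclass
class CVReport:
    """Apparent and cross-validated metrics per model."""

    summary: pd.DataFrame  # model_id, label, apparent_mse/r2, cv_mse/r2
    records: pd.DataFrame  # repeat, fold, model_id, mse, r2, n_val
    final_model: str       # smallest cross-validated MSE
    aggregation: str = "fold_local"

    def to_csv(self, path) -> None:
        self.summary.to_csv(path, index=False)

    def to_json(self, path) -> None:
        import json
        payload = {
            "final_model": self.final_model,
            "aggregation": self.aggregation,
            "summary": self.summary.to_dict(orient="records"),
            "records": self.records.to_dict(orient="records"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def _extract_xy(data) -> tuple[np.ndarray, np.ndarray]:
    """Accept either a feature table or an (X, y) pair."""
    if isinstance(data, pd.DataFrame):
        X = data[PREDICTOR_COLUMNS].to_numpy(dtype=float)
        y = data["pmd_observed"].to_numpy(dtype=float)
        return X, y
    X, y = data
    return np.asarray(X, dtype=float), np.asarray(y, dtype=float)


def partition_folds(n: int, folds: int, rng: np.random.Generator) -> list[np.ndarray]:
    """One random partition into near-equal folds (sizes differ by <= 1)."""
    if folds > n:
        raise ValueError(f"cannot split {n} observations into {folds} folds")
    perm = rng.permutation(n)
    return [np.sort(part) for part in np.array_split(perm, folds)]


def repeated_cv(data, specs: list[ModelSpec], cv_config: CVConfig) -> CVReport:
    """Repeated k-fold cross-validation of a model suite.

    All models see identical fold partitions within a repeat (the partition
    RNG stream is separate from the model RNG streams), so differences in
    the report reflect the models, not the splits.
    """
    X, y = _extract_xy(data)
    n = len(y)
    if not specs:
        raise ValueError("specs must be non-empty")
    if n // cv_config.folds < 2:
        raise ValueError(
            f"folds of size {n // cv_config.folds} are too small; "
            "need at least 2 observations per fold"
        )

    part_rng = np.random.default_rng(np.random.SeedSequence([cv_config.seed, 0x5bd1]))
    model_root = np.random.SeedSequence([cv_config.seed, 0xa2c7])
    model_seeds = model_root.spawn(cv_config.repeats * cv_config.folds + 1)

    records = []
    for rep in range(cv_config.repeats):
        folds = partition_folds(n, cv_config.folds, part_rng)
        for k, val_idx in enumerate(folds):
            train_idx = np.setdiff1d(np.arange(n), val_idx, assume_unique=False)
            seed_seq = model_seeds[rep * cv_config.folds + k]
            for spec in specs:
                fitted = models_mod.fit(spec, X[train_idx], y[train_idx],
                                        np.random.default_rng(seed_seq))
                pred = fitted.predict(X[val_idx])
                records.append({
                    "repeat": rep, "fold": k, "model_id": spec.model_id,
                    "mse": mse(y[val_idx], pred),
                    "r2": r_squared(y[val_idx], pred),
                    "n_val": len(val_idx),
                    "pooled_sse": float(np.sum((y[val_idx] - pred) ** 2)),
                })
    records_df = pd.DataFrame(records)

    rows = []
    apparent_seed = model_seeds[-1]
    for spec in specs:
        fitted = models_mod.fit(spec, X, y, np.random.default_rng(apparent_seed))
        pred = fitted.predict(X)
        sub = records_df[records_df.model_id == spec.model_id]
        if cv_config.aggregation == "fold_local":
            cv_mse = float(sub["mse"].mean())
            cv_r2 = float(sub["r2"].mean())
        else:  # pooled within repeat: all n held-out residuals of one repeat
            per_rep = sub.groupby("repeat")["pooled_sse"].sum() / n
            cv_mse = float(per_rep.mean())
            cv_r2 = 1.0 - cv_mse / float(np.var(y))
        rows.append({
            "model_id": spec.model_id, "label": spec.label,
            "apparent_mse": mse(y, pred), "apparent_r2": r_squared(y, pred),
            "cv_mse": cv_mse, "cv_r2": cv_r2,
        })
    summary = pd.DataFrame(rows)
    final = summary.loc[summary["cv_mse"].idxmin(), "model_id"]
    return CVReport(summary=summary,
                    records=records_df.drop(columns="pooled_sse"),
                    final_model=str(final),
                    aggregation=cv_config.aggregation)


def spearman_profile(features, pmd=None) -> pd.DataFrame:
    """Spearman ρ between each predictor bin and PMD.

    Returns a table with the white-ordered bin index (1 = whitest), the
    complementary black-ordered index, and ρ.  Constant bins yield NaN with
    a warning rather than being dropped silently.
    """
    if pmd is None:
        X, y = _extract_xy(features)
    else:
        X = np.asarray(features, dtype=float)
        y = np.asarray(pmd, dtype=float)
    if len(y) < 3:
        raise ValueError("need at least 3 observations for a correlation")
    rows = []
    n_bins_total = X.shape[1] + 1  # the omitted darkest bin completes the set
    for j in range(X.shape[1]):
        col = X[:, j]
        if np.ptp(col) == 0:
            logger.warning("bin %d is constant; Spearman rho undefined", j + 1)
            rho = np.nan
        else:
            rho = float(stats.spearmanr(col, y).statistic)
        rows.append({"bin_white_ordered": j + 1,
                     "bin_black_ordered": n_bins_total + 1 - (j + 1),
                     "spearman_rho": rho})
    return pd.DataFrame(rows)


def holdout_illustration(data, final_spec: ModelSpec, seed: int) -> tuple[pd.DataFrame, float]:
    """Single random 2/3 train - 1/3 validation split with the final model.

    Returns the (observed, predicted) pairs on the validation third and
    their out-of-sample R² — the scatter-plot illustration of how the
    final model behaves on future patients.
    """
    X, y = _extract_xy(data)
    n = len(y)
    if n < 30:
        raise ValueError("need at least 30 observations for the hold-out illustration")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train = (2 * n) // 3
    train_idx, val_idx = perm[:n_train], perm[n_train:]
    fitted = models_mod.fit(final_spec, X[train_idx], y[train_idx], rng)
    pred = fitted.predict(X[val_idx])
    table = pd.DataFrame({"index": val_idx, "observed": y[val_idx], "predicted": pred})
    return table.sort_values("index").reset_index(drop=True), r_squared(y[val_idx], pred)
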