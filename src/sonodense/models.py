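"""The eight density-prediction models M0-M7.

All models regress the PMD outcome on the 15 gray-level-bin predictors:

* M0 — null model (training mean, no predictors)
* M1 — ordinary least squares on all 15 bins
* M2 — M1 with stepwise backward elimination by AIC
* M3 — OLS with each bin expanded as a natural cubic spline with 2 df
* M4 — M3 with backward elimination of whole spline term groups by AIC
* M5 — lasso, penalty chosen by inner 10-fold CV (minimum-MSE rule)
* M6 — ridge, penalty chosen the same way
* M7 — random forest (500 trees, 5 candidate splits, minimum node size 5)

Every data-dependent choice — selected terms, spline knots, standardisation
constants, the penalty — is derived from the training data alone, so fitted
models can be evaluated on held-out data without leakage.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Any, Callable

import numpy as np
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import LassoCV
from sklearn.model_selection import KFold

logger = logging.getLogger(__name__)

MODEL_IDS = ("M0", "M1", "M2", "M3", "M4", "M5", "M6", "M7")
MODEL_LABELS = {
    "M0": "Null model",
    "M1": "Linear regression",
    "M2": "Linear regression with variable selection",
    "M3": "Cubic splines",
    "M4": "Cubic splines with variable selection",
    "M5": "Lasso",
    "M6": "Ridge regression",
    "M7": "Random forest",
}

MIN_TRAIN_N = 20


@dataclass(frozen=True)
class ModelSpec:
    """Identifier plus hyperparameters of one model family.

    Recognised hyperparameters:

    * ``penalty_grid`` (M5/M6): explicit array of penalties; default is a
      100-point log-spaced grid spanning six orders of magnitude below the
      data-driven maximal penalty.
    * ``inner_folds`` (M5/M6): folds of the penalty-selection CV, default 10.
    * ``n_trees``, ``mtry``, ``min_node`` (M7): defaults 500, 5, 5.
    * ``clip_predictions``: clip predictions to [0, 1]; default False.
    """

    model_id: str
    label: str = ""
    hyperparameters: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.model_id not in MODEL_IDS:
            raise ValueError(f"unknown model_id {self.model_id!r}; expected one of {MODEL_IDS}")
        if not self.label:
            object.__setattr__(self, "label", MODEL_LABELS[self.model_id])


def default_suite(model_ids: tuple[str, ...] = MODEL_IDS) -> list[ModelSpec]:
    return [ModelSpec(mid) for mid in model_ids]


@dataclass
class FittedModel:
    """Fitted state of one model; ``predict`` is a pure function of it."""

    model_id: str
    summary: dict[str, Any]
    _predict: Callable[[np.ndarray], np.ndarray]
    clip_predictions: bool = False

    def predict(self, X_new: np.ndarray) -> np.ndarray:
        X_new = np.asarray(X_new, dtype=float)
        if X_new.ndim != 2 or X_new.shape[1] != self.summary["n_predictors"]:
            raise ValueError(
                f"expected {self.summary['n_predictors']} predictor columns, "
                f"got shape {X_new.shape}"
            )
        pred = self._predict(X_new)
        if self.clip_predictions:
            pred = np.clip(pred, 0.0, 1.0)
        return pred


# ---------------------------------------------------------------- splines

def spline_training_stats(x: np.ndarray) -> tuple[float, float, float]:
    """Knots of the 2-df natural cubic spline: training min, median, max."""
    return float(np.min(x)), float(np.median(x)), float(np.max(x))


def spline_expand(x: np.ndarray, training_stats: tuple[float, float, float]) -> np.ndarray:
    """Natural (restricted) cubic spline basis with 2 degrees of freedom.

    Boundary knots at the training minimum and maximum, one interior knot
    at the training median.  Returns two columns: the linear term and the
    restricted truncated-power term, so linear functions are nested in the
    basis.  A constant training column (zero knot range) yields the column
    itself plus a zero column.
    """
    x = np.asarray(x, dtype=float)
    t1, t2, t3 = training_stats
    if t3 <= t1:
        logger.warning("constant predictor column: spline basis degenerates to linear")
        return np.column_stack([x, np.zeros_like(x)])
    if not t1 <= t2 <= t3:
        raise ValueError("spline knots must be ordered min <= median <= max")

    def pos3(v: np.ndarray) -> np.ndarray:
        return np.where(v > 0, v, 0.0) ** 3

    # Restricted cubic spline term (linear beyond the boundary knots)
    num = (pos3(x - t1)
           - pos3(x - t2) * (t3 - t1) / (t3 - t2)
           + pos3(x - t3) * (t2 - t1) / (t3 - t2))
    return np.column_stack([x, num / (t3 - t1) ** 2])


# ------------------------------------------------------------ OLS helpers

def _ols_fit(design: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Least-squares coefficients; minimum-norm (pseudo-inverse) if rank-deficient."""
    coef, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    if rank < design.shape[1]:
        logger.warning(
            "rank-deficient design (rank %d < %d columns); using pseudo-inverse fit",
            rank, design.shape[1],
        )
    return coef

def _with_intercept(X: np.ndarray) -> np.ndarray:
    return np.column_stack([np.ones(len(X)), X])


def _aic(rss: float, n: int, n_params: int) -> float:
    """Gaussian-likelihood AIC up to an additive constant (R's step convention)."""
    rss = max(rss, 1e-300)
    return n * np.log(rss / n) + 2.0 * n_params


def _rss(design: np.ndarray, y: np.ndarray) -> float:
    coef = _ols_fit(design, y)
    resid = y - design @ coef
    return float(resid @ resid)


def backward_eliminate(groups: list[np.ndarray], y: np.ndarray) -> list[int]:
    """Stepwise backward elimination of whole column groups by AIC.

    ``groups[i]`` holds the design columns of term ``i`` (a single predictor,
    or the 2-column spline basis of one predictor).  Starting from the full
    model, the drop that lowers AIC the most is applied until no drop helps.
    Returns the indices of retained groups (possibly empty: intercept only).
    """
    n = len(y)
    retained = list(range(len(groups)))

    def design_for(idx: list[int]) -> np.ndarray:
        if not idx:
            return np.ones((n, 1))
        return _with_intercept(np.column_stack([groups[i] for i in idx]))

    def aic_for(idx: list[int]) -> float:
        d = design_for(idx)
        return _aic(_rss(d, y), n, d.shape[1])

    current_aic = aic_for(retained)
    while retained:
        candidates = [(aic_for([i for i in retained if i != j]), j) for j in retained]
        best_aic, best_j = min(candidates)
        if best_aic < current_aic - 1e-10:
            retained = [i for i in retained if i != best_j]
            current_aic = best_aic
        else:
            break
    return retained


# ------------------------------------------------------- penalised models

def _standardize_stats(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)  # constant columns pass through centred
    return mu, sd


def _lasso_penalty_max(Xs: np.ndarray, y: np.ndarray) -> float:
    """Smallest penalty at which the lasso shrinks every slope to zero."""
    n = len(y)
    yc = y - y.mean()
    return float(np.max(np.abs(Xs.T @ yc)) / n)


def default_penalty_grid(Xs: np.ndarray, y: np.ndarray, model_id: str) -> np.ndarray:
    """100 log-spaced penalties over six orders below the maximal penalty.

    For the ridge no finite penalty annihilates the fit, so its grid is the
    lasso-derived maximum inflated by 10^3 (glmnet's convention), covering
    both near-OLS and heavily shrunk fits.
    """
    lam_max = max(_lasso_penalty_max(Xs, y), 1e-12)
    if model_id == "M6":
        lam_max *= 1e3
    return lam_max * np.logspace(0.0, -6.0, 100)


def _ridge_coef_path(Xs: np.ndarray, yc: np.ndarray, alphas: np.ndarray) -> np.ndarray:
    """Ridge coefficients for every penalty at once via one SVD.

    Minimises ||yc - Xs b||^2 + n*alpha*||b||^2 on centred data (the same
    per-observation penalty scale as the lasso).  Returns shape (p, n_alphas).
    """
    n = len(yc)
    U, s, Vt = np.linalg.svd(Xs, full_matrices=False)
    uty = U.T @ yc
    denom = s[:, None] ** 2 + n * alphas[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        shrink = np.where(denom > 0, s[:, None] * uty[:, None] / denom, 0.0)
    return Vt.T @ shrink


def _fit_ridge_cv(X: np.ndarray, y: np.ndarray, alphas: np.ndarray,
                  inner_folds: int, rng: np.random.Generator):
    mu, sd = _standardize_stats(X)
    Xs = (X - mu) / sd
    n = len(y)
    kf = KFold(n_splits=inner_folds, shuffle=True,
               random_state=int(rng.integers(2**31)))
    cv_sse = np.zeros(len(alphas))
    for tr, va in kf.split(Xs):
        ytr_mean = y[tr].mean()
        xtr_mean = Xs[tr].mean(axis=0)
        B = _ridge_coef_path(Xs[tr] - xtr_mean, y[tr] - ytr_mean, alphas)
        pred = (Xs[va] - xtr_mean) @ B + ytr_mean
        cv_sse += ((pred - y[va][:, None]) ** 2).sum(axis=0)
    best = int(np.argmin(cv_sse / n))
    alpha = float(alphas[best])
    xmean = Xs.mean(axis=0)
    coef = _ridge_coef_path(Xs - xmean, y - y.mean(), np.array([alpha]))[:, 0]
    intercept = y.mean() - float(xmean @ coef)

    def predict(X_new: np.ndarray) -> np.ndarray:
        return ((X_new - mu) / sd) @ coef + intercept

    return predict, alpha, coef


def _fit_lasso_cv(X: np.ndarray, y: np.ndarray, alphas: np.ndarray,
                  inner_folds: int, rng: np.random.Generator):
    mu, sd = _standardize_stats(X)
    Xs = (X - mu) / sd
    kf = KFold(n_splits=inner_folds, shuffle=True,
               random_state=int(rng.integers(2**31)))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # convergence chatter at tiny penalties
        model = LassoCV(alphas=np.sort(alphas)[::-1], cv=kf,
                        precompute=True, max_iter=2000).fit(Xs, y)

    def predict(X_new: np.ndarray) -> np.ndarray:
        return model.predict((X_new - mu) / sd)

    return predict, float(model.alpha_), model.coef_.copy()


# ----------------------------------------------------------------- fitting

def fit(spec: ModelSpec, X: np.ndarray, y: np.ndarray,
        rng_state: np.random.Generator | int) -> FittedModel:
    """Fit one model; every data-dependent choice uses (X, y) only."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or len(X) != len(y):
        raise ValueError("X must be 2-D with one row per element of y")
    if len(y) < MIN_TRAIN_N:
        raise ValueError(f"need at least {MIN_TRAIN_N} training rows, got {len(y)}")
    if np.isnan(X).any() or np.isnan(y).any():
        raise ValueError("missing values are not supported")
    rng = (rng_state if isinstance(rng_state, np.random.Generator)
           else np.random.default_rng(rng_state))
    hp = spec.hyperparameters
    p = X.shape[1]
    summary: dict[str, Any] = {"model_id": spec.model_id, "n_predictors": p,
                               "n_train": len(y)}
    mid = spec.model_id

    if mid == "M0":
        mean_y = float(y.mean())
        summary["mean"] = mean_y
        predict = lambda Xn: np.full(len(Xn), mean_y)

    elif mid in ("M1", "M2"):
        if mid == "M2":
            groups = [X[:, [j]] for j in range(p)]
            kept = backward_eliminate(groups, y)
        else:
            kept = list(range(p))
        design = _with_intercept(X[:, kept]) if kept else np.ones((len(y), 1))
        coef = _ols_fit(design, y)
        summary["terms_retained"] = kept
        summary["coefficients"] = coef.tolist()
        def predict(Xn, kept=kept, coef=coef):
            d = _with_intercept(Xn[:, kept]) if kept else np.ones((len(Xn), 1))
            return d @ coef

    elif mid in ("M3", "M4"):
        stats = [spline_training_stats(X[:, j]) for j in range(p)]
        groups = [spline_expand(X[:, j], stats[j]) for j in range(p)]
        kept = backward_eliminate(groups, y) if mid == "M4" else list(range(p))
        design = (_with_intercept(np.column_stack([groups[j] for j in kept]))
                  if kept else np.ones((len(y), 1)))
        coef = _ols_fit(design, y)
        summary["terms_retained"] = kept
        summary["coefficients"] = coef.tolist()
        summary["spline_knots"] = [stats[j] for j in kept]
        def predict(Xn, kept=kept, coef=coef, stats=stats):
            if not kept:
                return np.full(len(Xn), coef[0])
            cols = [spline_expand(Xn[:, j], stats[j]) for j in kept]
            return _with_intercept(np.column_stack(cols)) @ coef

    elif mid in ("M5", "M6"):
        inner = int(hp.get("inner_folds", 10))
        mu, sd = _standardize_stats(X)
        grid = hp.get("penalty_grid")
        alphas = (np.asarray(grid, dtype=float) if grid is not None
                  else default_penalty_grid((X - mu) / sd, y, mid))
        if mid == "M5":
            predict, alpha, coef = _fit_lasso_cv(X, y, alphas, inner, rng)
        else:
            predict, alpha, coef = _fit_ridge_cv(X, y, alphas, inner, rng)
        summary["penalty"] = alpha
        summary["n_nonzero"] = int(np.count_nonzero(coef))

    elif mid == "M7":
        # "minimum node size" in the regression-forest convention gates the
        # splitting of a node; children may end up smaller, so it maps to
        # min_samples_split rather than min_samples_leaf.
        forest = RandomForestRegressor(
            n_estimators=int(hp.get("n_trees", 500)),
            max_features=int(hp.get("mtry", max(1, p // 3))),
            min_samples_split=int(hp.get("min_node", 5)) + 1,
            random_state=int(rng.integers(2**31)),
            n_jobs=1,
        ).fit(X, y)
        summary["n_trees"] = forest.n_estimators
        predict = forest.predict

    else:  # pragma: no cover - guarded by ModelSpec
        raise ValueError(f"unknown model {mid}")

    return FittedModel(
        model_id=mid,
        summary=summary,
        _predict=predict,
        clip_predictions=bool(hp.get("clip_predictions", False)),
    )
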