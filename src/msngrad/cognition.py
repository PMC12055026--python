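"""Gradient-cognition association and prediction.

Two analyses link gradients to cognition in the patient group:

* partial Pearson correlation between class-level gradient means and
  each cognitive score, controlling age, sex and education;
* support vector regression (linear kernel) predicting each score from
  region-level gradient-1 scores in a nested 5-fold cross-validation,
  with observed-vs-predicted Pearson r as the performance measure and a
  label-permutation test for significance.  Feature scaling and
  hyperparameter tuning happen strictly inside training folds.

A comparator feature set — regional MSN strength (per-region sum of
correlation coefficients) — is evaluated with identical folds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.model_selection import GridSearchCV, KFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR

__all__ = [
    "partial_correlation",
    "PredictionResult",
    "svr_predict_cv",
    "permutation_p",
    "compare_feature_sets",
]

DEFAULT_C_GRID = (0.01, 0.1, 1.0, 10.0, 100.0)
DEFAULT_EPS_GRID = (0.01, 0.1, 1.0)


def partial_correlation(
    x: np.ndarray, y: np.ndarray, covariates: np.ndarray | None = None
) -> tuple[float, float]:
    """Pearson correlation of x and y after regressing out covariates.

    Both variables are residualized on [intercept, covariates] by OLS;
    the two-sided p uses the t transform with df = n - n_covariates - 2.
    With no covariates this is the plain Pearson correlation.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    n = x.size
    if y.size != n:
        raise ValueError("x and y must have the same length")
    if covariates is None or (hasattr(covariates, "size") and covariates.size == 0):
        c = np.empty((n, 0))
    else:
        c = np.asarray(covariates, dtype=float)
        if c.ndim == 1:
            c = c[:, None]
    k = c.shape[1]
    if n <= k + 2:
        raise ValueError(f"need n > n_covariates + 2, got n={n}, k={k}")
    design = np.column_stack([np.ones(n), c])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("rank-deficient covariate matrix")
    coef, *_ = np.linalg.lstsq(design, np.column_stack([x, y]), rcond=None)
    resid = np.column_stack([x, y]) - design @ coef
    rx, ry = resid[:, 0], resid[:, 1]
    r = float(rx @ ry / np.sqrt((rx @ rx) * (ry @ ry)))
    df = n - k - 2
    r_clip = min(max(r, -1 + 1e-15), 1 - 1e-15)
    t = r_clip * np.sqrt(df / (1.0 - r_clip**2))
    p = float(2.0 * sps.t.sf(abs(t), df))
    return r, p


@dataclass
class PredictionResult:
    """Out-of-fold prediction performance for one target."""

    r: float
    predictions: np.ndarray
    fold_assignments: np.ndarray
    best_params: list[dict] = field(default_factory=list)
    permutation_p: float | None = None


def _inner_seed(seed: int) -> int:
    return int(np.random.SeedSequence(seed).generate_state(1)[0] % (2**31))


def svr_predict_cv(
    features: np.ndarray,
    target: np.ndarray,
    n_outer: int = 5,
    n_inner: int = 5,
    c_grid: tuple[float, ...] = DEFAULT_C_GRID,
    eps_grid: tuple[float, ...] = DEFAULT_EPS_GRID,
    seed: int = 0,
) -> PredictionResult:
    """Nested cross-validated SVR prediction of a cognitive score.

    Per outer fold, a grid search over (C, epsilon) with ``n_inner``-fold
    inner CV selects hyperparameters on the training subjects only; the
    tuned pipeline (standardization + linear SVR) predicts the held-out
    fold.  Returns the Pearson r between the target and the concatenated
    out-of-fold predictions.
    """
    x = np.asarray(features, dtype=float)
    y = np.asarray(target, dtype=float).ravel()
    if x.shape[0] != y.size:
        raise ValueError("features and target must have the same number of subjects")
    if y.size < 5 * n_outer:
        raise ValueError(f"need at least {5 * n_outer} subjects for {n_outer}-fold nested CV")
    if np.ptp(y) == 0:
        raise ValueError("constant target cannot be predicted")

    outer = KFold(n_splits=n_outer, shuffle=True, random_state=seed % (2**31))
    inner_rs = _inner_seed(seed + 1)
    pred = np.empty_like(y)
    folds = np.empty(y.size, dtype=int)
    best = []
    for fold, (tr, te) in enumerate(outer.split(x)):
        pipe = Pipeline(
            [("scale", StandardScaler()), ("svr", SVR(kernel="linear"))]
        )
        grid = {"svr__C": list(c_grid), "svr__epsilon": list(eps_grid)}
        if len(c_grid) * len(eps_grid) > 1:
            search = GridSearchCV(
                pipe,
                grid,
                cv=KFold(n_splits=n_inner, shuffle=True, random_state=inner_rs),
                scoring="neg_mean_squared_error",
                n_jobs=1,
            )
            search.fit(x[tr], y[tr])
            model = search.best_estimator_
            best.append(search.best_params_)
        else:
            pipe.set_params(svr__C=c_grid[0], svr__epsilon=eps_grid[0])
            model = pipe.fit(x[tr], y[tr])
            best.append({"svr__C": c_grid[0], "svr__epsilon": eps_grid[0]})
        pred[te] = model.predict(x[te])
        folds[te] = fold
    r = float(sps.pearsonr(y, pred)[0])
    return PredictionResult(r=r, predictions=pred, fold_assignments=folds, best_params=best)


def permutation_p(
    observed_r: float,
    features: np.ndarray,
    target: np.ndarray,
    n_perm: int = 1000,
    seed: int = 0,
    cv_seed: int = 0,
    **cv_kwargs,
) -> float:
    """Label-permutation significance of an out-of-fold prediction r.

    The target vector is permuted and the full nested-CV pipeline re-run
    per permutation; ``p = (1 + #{r_perm >= r_obs}) / (1 + n_perm)``.
    ``cv_seed`` fixes the fold structure (use the observed run's seed).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    y = np.asarray(target, dtype=float).ravel()
    count = 0
    for _ in range(n_perm):
        r_perm = svr_predict_cv(features, rng.permutation(y), seed=cv_seed, **cv_kwargs).r
        if r_perm >= observed_r:
            count += 1
    return (1 + count) / (1 + n_perm)


def compare_feature_sets(
    gradient_features: np.ndarray,
    strength_features: np.ndarray,
    targets: pd.DataFrame,
    n_perm: int = 0,
    seed: int = 0,
    **cv_kwargs,
) -> pd.DataFrame:
    """Predict every score from both feature sets with identical folds.

    Returns a tidy report (score, feature_set, r, p, n); permutation p
    is computed when ``n_perm > 0``.
    """
    g = np.asarray(gradient_features, dtype=float)
    s = np.asarray(strength_features, dtype=float)
    if g.shape[0] != s.shape[0] or g.shape[0] != len(targets):
        raise ValueError("feature sets and targets must cover the same subjects")
    rows = []
    for score in targets.columns:
        y = targets[score].to_numpy(dtype=float)
        for name, feats in (("gradient", g), ("strength", s)):
            res = svr_predict_cv(feats, y, seed=seed, **cv_kwargs)
            p = (
                permutation_p(
                    res.r, feats, y, n_perm=n_perm, seed=seed + 1,
                    cv_seed=seed, **cv_kwargs,
                )
                if n_perm > 0
                else np.nan
            )
            rows.append(
                {"score": score, "feature_set": name, "r": res.r, "p": p, "n": len(y)}
            )
    return pd.DataFrame(rows)
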