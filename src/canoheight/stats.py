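"""Plot-level canopy statistics and the Lorey's-height evaluation models.

Contains the threshold difference statistics (mean_k and p_k of
|corrected - conventional| exceedances), LiDAR height percentiles above
the 1.8 m shrub cutoff, Lorey's height (basal-area-weighted stand
height), a forward-stepwise percentile regression selected by K-fold
cross-validated R^2, and the slope-vs-p_k linear regression used to
quantify how terrain drives normalization differences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.base import BaseEstimator, RegressorMixin

DEFAULT_THRESHOLDS = (0.3, 0.5, 0.8, 1.0, 1.2, 1.5)
PERCENTILE_NAMES = tuple(f"h{k}0" for k in range(1, 10)) + ("hmean",)


@dataclass
class DifferenceStats:
    """Exceedance statistics of |corrected - conventional| heights.

    For each threshold k: p_k is the fraction of points with |diff| > k
    and mean_k the mean |diff| over that set (0 when the set is empty).
    """

    thresholds: np.ndarray
    mean_k: np.ndarray
    p_k: np.ndarray
    n: int

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"threshold_m": self.thresholds,
                             "mean_k_m": self.mean_k,
                             "p_k": self.p_k})


def difference_stats(conventional, corrected,
                     thresholds=DEFAULT_THRESHOLDS) -> DifferenceStats:
    conventional = np.asarray(conventional, dtype=float)
    corrected = np.asarray(corrected, dtype=float)
    if conventional.size != corrected.size:
        raise ValueError("height vectors must have equal length")
    if conventional.size == 0:
        raise ValueError("empty height vectors")
    diff = np.abs(corrected - conventional)
    ks = np.asarray(thresholds, dtype=float)
    p_k = np.empty(ks.size)
    mean_k = np.empty(ks.size)
    for i, k in enumerate(ks):
        over = diff > k
        p_k[i] = over.mean()
        mean_k[i] = diff[over].mean() if over.any() else 0.0
    return DifferenceStats(ks, mean_k, p_k, diff.size)


def height_percentiles(heights, above: float = 1.8) -> pd.Series:
    """h10..h90 (linear-interpolation quantiles) and hmean of the heights
    strictly above the cutoff."""
    heights = np.asarray(heights, dtype=float)
    sub = heights[heights > above]
    if sub.size == 0:
        raise ValueError(f"no heights above {above} m")
    vals = np.percentile(sub, np.arange(10, 100, 10))
    return pd.Series(np.append(vals, sub.mean()), index=list(PERCENTILE_NAMES))


def lorey_height(dbh_cm, height_m) -> float:
    """Basal-area-weighted mean stand height Lh = sum(G_i h_i)/sum(G_i)
    with G_i = pi * (dbh_i / 200)^2 in m^2 (dbh in cm)."""
    dbh = np.asarray(dbh_cm, dtype=float)
    h = np.asarray(height_m, dtype=float)
    if dbh.size == 0:
        raise ValueError("need at least one stem")
    if np.any(dbh <= 0):
        raise ValueError("all DBH values must be positive")
    G = np.pi * (dbh / 200.0) ** 2
    return float((G * h).sum() / G.sum())


# ---------------------------------------------------------------------------
# stepwise percentile regression
# ---------------------------------------------------------------------------

def _stratified_folds(y: np.ndarray, k: int, seed: int) -> np.ndarray:
    """Deterministic fold labels, stratified by response rank: sort by y,
    then shuffle fold labels within consecutive blocks of k ranks."""
    rng = np.random.default_rng(seed)
    order = np.argsort(y, kind="stable")
    folds = np.empty(y.size, dtype=int)
    labels = np.arange(k)
    for start in range(0, y.size, k):
        block = order[start:start + k]
        folds[block] = rng.permutation(labels)[:block.size]
    return folds


def _ols(X: np.ndarray, y: np.ndarray, names):
    A = np.column_stack([np.ones(len(y)), X])
    if np.linalg.matrix_rank(A) < A.shape[1]:
        raise ValueError(f"singular design: collinear terms {list(names)}")
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    return beta


def _cv_r2(X: np.ndarray, y: np.ndarray, folds: np.ndarray) -> float:
    """Pooled out-of-fold R^2 (1 - SSres/SStot over all held-out rows)."""
    pred = np.empty_like(y)
    for f in np.unique(folds):
        test = folds == f
        train = ~test
        A_tr = np.column_stack([np.ones(train.sum()), X[train]])
        beta, *_ = np.linalg.lstsq(A_tr, y[train], rcond=None)
        A_te = np.column_stack([np.ones(test.sum()), X[test]])
        pred[test] = A_te @ beta
    ss_tot = np.sum((y - y.mean()) ** 2)
    return 1.0 - np.sum((y - pred) ** 2) / ss_tot


class StepwiseLoreyRegressor(BaseEstimator, RegressorMixin):
    """Forward-stepwise OLS of Lorey's height on LiDAR height percentiles.

    Candidate predictors are the ten standard metrics h10..h90 and hmean.
    At each step the predictor that most improves the pooled K-fold
    validation R^2 is added; selection stops when no addition improves
    it by at least ``min_improvement`` (a small positive floor guards
    against chaining chance validation gains on noise).  Fold assignment
    is seeded and stratified by response rank so the fit is
    deterministic.

    Attributes (after fit)
    ----------------------
    selected_features_ : list of chosen predictor names, in entry order.
    intercept_, coef_ : OLS coefficients of the final model.
    r2_, adj_r2_, rmse_ : in-sample fit statistics.
    cv_r2_ : K-fold validation R^2 of the final model.
    """

    def __init__(self, k_folds: int = 10, random_state: int = 0,
                 candidates=PERCENTILE_NAMES, min_improvement: float = 0.01):
        self.k_folds = k_folds
        self.random_state = random_state
        self.candidates = candidates
        self.min_improvement = min_improvement

    def fit(self, X, y):
        if isinstance(X, pd.DataFrame):
            names = [c for c in self.candidates if c in X.columns]
            if not names:
                names = list(X.columns)
            Xa = X[names].to_numpy(dtype=float)
        else:
            Xa = np.asarray(X, dtype=float)
            names = list(self.candidates)[:Xa.shape[1]] \
                if Xa.shape[1] <= len(self.candidates) \
                else [f"x{i}" for i in range(Xa.shape[1])]
        y = np.asarray(y, dtype=float)
        if len(y) < self.k_folds:
            raise ValueError("need at least k_folds observations")
        folds = _stratified_folds(y, self.k_folds, self.random_state)

        selected: list[int] = []
        remaining = list(range(len(names)))
        best_cv = _cv_r2(np.empty((len(y), 0)), y, folds)  # intercept-only
        improved = True
        while improved and remaining:
            improved = False
            best_j, best_score = None, best_cv + self.min_improvement
            for j in remaining:
                score = _cv_r2(Xa[:, selected + [j]], y, folds)
                if score > best_score:
                    best_j, best_score = j, score
            if best_j is not None:
                selected.append(best_j)
                remaining.remove(best_j)
                best_cv = best_score
                improved = True

        self.selected_features_ = [names[j] for j in selected]
        Xs = Xa[:, selected]
        beta = _ols(Xs, y, self.selected_features_)
        self.intercept_ = float(beta[0])
        self.coef_ = beta[1:]
        pred = beta[0] + Xs @ beta[1:]
        ss_res = np.sum((y - pred) ** 2)
        ss_tot = np.sum((y - y.mean()) ** 2)
        n, p = len(y), len(selected)
        self.r2_ = 1.0 - ss_res / ss_tot
        self.adj_r2_ = 1.0 - (1.0 - self.r2_) * (n - 1) / max(n - p - 1, 1)
        self.rmse_ = float(np.sqrt(ss_res / n))
        self.cv_r2_ = float(best_cv)
        self._names = names
        return self

    def predict(self, X):
        if isinstance(X, pd.DataFrame):
            Xs = X[self.selected_features_].to_numpy(dtype=float)
        else:
            Xa = np.asarray(X, dtype=float)
            cols = [self._names.index(f) for f in self.selected_features_]
            Xs = Xa[:, cols]
        return self.intercept_ + Xs @ self.coef_

    def report(self) -> dict:
        return {"selected": list(self.selected_features_),
                "intercept": self.intercept_,
                "coefficients": dict(zip(self.selected_features_,
                                         map(float, self.coef_))),
                "r2": float(self.r2_), "adj_r2": float(self.adj_r2_),
                "rmse": self.rmse_, "cv_r2": self.cv_r2_}


def fit_lorey_model(plots: pd.DataFrame, k_folds: int = 10,
                    response: str = "lorey",
                    seed: int = 0) -> StepwiseLoreyRegressor:
    """Fit the stepwise percentile model on a plot table with columns
    h10..h90, hmean and the Lorey's-height response."""
    model = StepwiseLoreyRegressor(k_folds=k_folds, random_state=seed)
    return model.fit(plots, plots[response].to_numpy(dtype=float))


def slope_proportion_regression(slopes_deg, p_values):
    """OLS of the exceedance proportion p_k on plot slope gradient.

    Returns ``(slope_coefficient, intercept, r_squared)``.  A constant
    response yields R^2 = 0 by convention; constant slopes raise.
    """
    s = np.asarray(slopes_deg, dtype=float)
    p = np.asarray(p_values, dtype=float)
    if s.size < 3:
        raise ValueError("need at least 3 plots")
    if np.allclose(s, s[0]):
        raise ValueError("slope gradient has zero variance")
    if np.allclose(p, p[0]):
        return 0.0, float(p[0]), 0.0
    res = sps.linregress(s, p)
    return float(res.slope), float(res.intercept), float(res.rvalue ** 2)
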