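"""Quantile regression forest member (Meinshausen conditional quantiles).

The point forecast is the plain bagged-forest mean over n trees; the
forecast distribution comes from the weighted empirical CDF of the
training targets, with observation weights equal to the average co-leaf
frequency with the query point across trees.  Defaults follow the study
configuration: n = 2000 trees, m = 4 predictors sampled per split
(sqrt of the 16 available predictors).
"""

from __future__ import annotations

import numpy as np
from sklearn.ensemble import RandomForestRegressor

from .forecast import CENTILES, ForecastDistribution

__all__ = ["QuantileForest", "weighted_quantile_interp"]

DEFAULT_N_TREES = 2000
DEFAULT_M_TRY = 4
DEFAULT_MIN_LEAF = 10


def weighted_quantile_interp(
    values: np.ndarray, weights: np.ndarray, percentiles: np.ndarray
) -> np.ndarray:
    """Interpolated weighted quantiles.

    Generalizes the usual linear-interpolation sample quantile: plotting
    position of the i-th ranked value is ``(C_i - w_i) / (W - w_i)`` with
    ``C_i`` the cumulative weight, which reduces to ``(i-1)/(n-1)`` for
    equal weights.
    """
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    p = np.atleast_1d(np.asarray(percentiles, dtype=float)) / 100.0
    keep = weights > 0
    values, weights = values[keep], weights[keep]
    if values.size == 0:
        raise ValueError("no positive-weight observations")
    if values.size == 1:
        return np.full(p.shape, values[0])
    order = np.argsort(values, kind="stable")
    v = values[order]
    w = weights[order]
    W = w.sum()
    c = np.cumsum(w)
    pos = (c - w) / (W - w)
    pos = np.maximum.accumulate(pos)  # guard monotonicity under unequal weights
    return np.interp(p, pos, v)


class QuantileForest:
    """Random forest with retained leaf maps for conditional quantiles."""

    name = "qrf"

    def __init__(
        self,
        n_trees: int = DEFAULT_N_TREES,
        m_try: int = DEFAULT_M_TRY,
        min_samples_leaf: int = DEFAULT_MIN_LEAF,
        random_state: int | None = None,
        oob_score: bool = False,
    ):
        self.n_trees = n_trees
        self.m_try = m_try
        self.min_samples_leaf = min_samples_leaf
        self.random_state = random_state
        self.oob_score = oob_score
        self._forest: RandomForestRegressor | None = None
        self._train_leaves: np.ndarray | None = None
        self._train_y: np.ndarray | None = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "QuantileForest":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.shape[0] < 30:
            raise ValueError("need at least 30 training rows")
        if self.m_try > X.shape[1]:
            raise ValueError(
                f"m_try={self.m_try} exceeds the {X.shape[1]} available predictors"
            )
        self._forest = RandomForestRegressor(
            n_estimators=self.n_trees,
            max_features=self.m_try,
            min_samples_leaf=self.min_samples_leaf,
            bootstrap=True,
            oob_score=self.oob_score,
            random_state=self.random_state,
            n_jobs=1,
        ).fit(X, y)
        self._train_leaves = self._forest.apply(X)  # (n_train, n_trees)
        self._train_y = y
        return self

    def _co_leaf_weights(self, x: np.ndarray) -> np.ndarray:
        """Average co-leaf frequency of each training row with query x."""
        assert self._forest is not None
        leaves_q = self._forest.apply(x.reshape(1, -1))[0]  # (n_trees,)
        same = self._train_leaves == leaves_q[None, :]
        counts = same.sum(axis=0).astype(float)  # leaf sizes per tree
        with np.errstate(divide="ignore", invalid="ignore"):
            contrib = np.where(same, 1.0 / counts[None, :], 0.0)
        return contrib.mean(axis=1)

    def predict_distribution_many(
        self, X: np.ndarray, made_at_weeks: np.ndarray, horizon: int = 1
    ) -> list[ForecastDistribution]:
        """Batch version: one forest pass for points, apply and weights."""
        if self._forest is None:
            raise RuntimeError("fit() must be called first")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        points = self._forest.predict(X)
        leaves_q = self._forest.apply(X)  # (n_query, n_trees)
        # co-leaf membership: (n_train, n_query, n_trees)
        same = self._train_leaves[:, None, :] == leaves_q[None, :, :]
        counts = same.sum(axis=0).astype(float)  # leaf size per (query, tree)
        with np.errstate(divide="ignore", invalid="ignore"):
            weights = (same / counts[None, :, :]).mean(axis=2)  # (n_train, n_query)
        out = []
        for k, t in enumerate(made_at_weeks):
            q = weighted_quantile_interp(self._train_y, weights[:, k], CENTILES)
            out.append(
                ForecastDistribution(
                    made_at_week=int(t), horizon=horizon, point=float(points[k]),
                    centiles=q, model=self.name,
                ).floored()
            )
        return out

    def predict_distribution(
        self, x: np.ndarray, made_at_week: int = 0, horizon: int = 1
    ) -> ForecastDistribution:
        """Forest-mean point plus Meinshausen weighted-CDF centiles."""
        return self.predict_distribution_many(
            np.asarray(x, dtype=float).reshape(1, -1), np.array([made_at_week]),
            horizon,
        )[0]

    def oob_rmse(self) -> float:
        """Out-of-bag RMSE (available when fitted with ``oob_score=True``)."""
        if self._forest is None or not self.oob_score:
            raise RuntimeError("fit with oob_score=True first")
        resid = self._train_y - self._forest.oob_prediction_
        return float(np.sqrt(np.mean(resid**2)))
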