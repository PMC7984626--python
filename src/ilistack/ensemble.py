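"""Stacked and naive ensembles.

Stacking weights solve the simplex-constrained least-squares problem

    min_w (1/H) sum_t (y_t - sum_m w_m fhat_m(X_t | theta_{-t}))^2
    s.t. sum_m w_m = 1,  w_m >= 0,

where each row's member predictions come from models trained without the
flu season containing that row.  The ensemble forecast is the weighted
average of member points, and its "back-of-the-envelope" distribution the
weighted average of member centile vectors.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .forecast import ForecastDistribution

__all__ = [
    "WeightVector",
    "StackingPanel",
    "simplex_lstsq",
    "stack_weights",
    "naive_weights",
    "ensemble_forecast",
]

_RIDGE = 1e-9  # minimum-norm tie-break on flat optimum directions


@dataclasses.dataclass
class WeightVector:
    """Nonnegative member weights summing to one."""

    w: np.ndarray
    members: tuple[str, ...]
    horizon: int | None = None
    heldout_season: str | None = None
    degenerate: bool = False

    def __post_init__(self):
        self.w = np.asarray(self.w, dtype=float)
        if np.any(self.w < -1e-10):
            raise ValueError("weights must be nonnegative")
        if abs(self.w.sum() - 1.0) > 1e-8:
            raise ValueError("weights must sum to 1")

    def as_series(self) -> pd.Series:
        return pd.Series(self.w, index=list(self.members))


@dataclasses.dataclass
class StackingPanel:
    """Held-out member predictions and observations, one row per week."""

    predictions: pd.DataFrame  # columns = member names
    observed: np.ndarray
    horizon: int
    seasons: np.ndarray  # season id per row

    def __len__(self) -> int:
        return len(self.observed)

    @property
    def members(self) -> tuple[str, ...]:
        return tuple(self.predictions.columns)

    def objective(self, w: np.ndarray) -> float:
        """Mean squared panel error of a candidate weight vector."""
        resid = self.observed - self.predictions.to_numpy() @ np.asarray(w, float)
        return float(np.mean(resid**2))


def simplex_lstsq(F: np.ndarray, y: np.ndarray, ridge: float = _RIDGE) -> np.ndarray:
    """Exact simplex-constrained least squares via SLSQP multistart.

    Starts from the equal-weight point and every unit vector; a tiny ridge
    steers flat optima to the minimum-norm solution.  Deterministic given
    the inputs.
    """
    F = np.asarray(F, dtype=float)
    y = np.asarray(y, dtype=float)
    H, M = F.shape
    if H < M:
        raise ValueError(f"panel has {H} rows; need at least {M}")

    G = (F.T @ F) / H + ridge * np.eye(M)
    b = (F.T @ y) / H
    c = float(y @ y) / H

    def obj(w):
        return float(w @ G @ w - 2.0 * b @ w + c)

    def grad(w):
        return 2.0 * (G @ w - b)

    cons = [{"type": "eq", "fun": lambda w: w.sum() - 1.0,
             "jac": lambda w: np.ones(M)}]
    bounds = [(0.0, 1.0)] * M
    starts = [np.full(M, 1.0 / M)] + [np.eye(M)[m] for m in range(M)]
    best = None
    for x0 in starts:
        r = minimize(obj, x0, jac=grad, method="SLSQP", bounds=bounds,
                     constraints=cons, options={"maxiter": 500, "ftol": 1e-14})
        if best is None or r.fun < best.fun - 1e-15:
            best = r
    w = np.clip(best.x, 0.0, None)
    return w / w.sum()


def stack_weights(panel: StackingPanel) -> WeightVector:
    """Solve the stacking problem on a held-out prediction panel.

    Degenerate panels (all member columns identical) return equal weights
    with the ``degenerate`` flag set.
    """
    F = panel.predictions.to_numpy(dtype=float)
    M = F.shape[1]
    if np.allclose(F, F[:, [0]]):
        return WeightVector(
            w=np.full(M, 1.0 / M), members=panel.members,
            horizon=panel.horizon, degenerate=True,
        )
    w = simplex_lstsq(F, panel.observed)
    return WeightVector(w=w, members=panel.members, horizon=panel.horizon)


def naive_weights(M: int, members: tuple[str, ...] | None = None) -> WeightVector:
    """Equal weights 1/M on each member."""
    if M < 1:
        raise ValueError("M must be >= 1")
    if members is None:
        members = tuple(f"m{i}" for i in range(M))
    return WeightVector(w=np.full(M, 1.0 / M), members=members)


def ensemble_forecast(
    w: WeightVector, member_forecasts: list[ForecastDistribution], model: str = "se"
) -> ForecastDistribution:
    """Weighted average of member points and of member centile vectors."""
    if len(member_forecasts) != len(w.w):
        raise ValueError("one forecast per weight required")
    h = {f.horizon for f in member_forecasts}
    t = {f.made_at_week for f in member_forecasts}
    if len(h) != 1 or len(t) != 1:
        raise ValueError("member forecasts must share made_at_week and horizon")
    point = float(sum(wi * f.point for wi, f in zip(w.w, member_forecasts)))
    centiles = np.sum(
        [wi * f.centiles for wi, f in zip(w.w, member_forecasts)], axis=0
    )
    return ForecastDistribution(
        made_at_week=t.pop(), horizon=h.pop(), point=point,
        centiles=centiles, model=model,
    )
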