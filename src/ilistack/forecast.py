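"""The universal probabilistic-forecast container shared by all members."""

from __future__ import annotations

import dataclasses

import numpy as np

__all__ = ["ForecastDistribution", "CENTILES"]

CENTILES = np.arange(1, 100)  # 1..99


@dataclasses.dataclass
class ForecastDistribution:
    """Point forecast plus a 99-centile vector for one (origin, horizon).

    ``made_at_week`` is the 0-based position of the forecast origin in the
    weekly record; ``horizon`` is 1-4 weeks ahead.  ``centiles[c-1]`` is the
    c-th centile; the vector is nondecreasing and, for count outputs,
    floored at zero on construction.
    """

    made_at_week: int
    horizon: int
    point: float
    centiles: np.ndarray
    model: str = ""

    def __post_init__(self):
        self.centiles = np.asarray(self.centiles, dtype=float)
        if self.centiles.shape != (99,):
            raise ValueError("centiles must be a vector of length 99")
        if np.any(np.diff(self.centiles) < -1e-8):
            raise ValueError("centile vector must be nondecreasing")
        if self.horizon not in (1, 2, 3, 4):
            raise ValueError("horizon must be in {1, 2, 3, 4}")

    def quantile(self, c: int) -> float:
        """The c-th centile, c in 1..99."""
        return float(self.centiles[c - 1])

    def interval(self, level: float = 0.90) -> tuple[float, float]:
        """Central prediction interval from the centile vector.

        A 90% interval is (q05, q95); the level must map onto whole
        centiles.
        """
        tail = (1.0 - level) / 2.0 * 100.0
        lo = round(tail)
        if not np.isclose(tail, lo) or lo < 1:
            raise ValueError(f"level {level} does not map onto whole centiles")
        return float(self.centiles[lo - 1]), float(self.centiles[99 - lo])

    def floored(self) -> "ForecastDistribution":
        """Copy with centiles floored at zero (count scale).

        The point is left untouched internally; reports floor it on
        output.
        """
        return ForecastDistribution(
            made_at_week=self.made_at_week,
            horizon=self.horizon,
            point=self.point,
            centiles=np.maximum(self.centiles, 0.0),
            model=self.model,
        )


def gaussian_centiles(point: float, sd: float) -> np.ndarray:
    """Centiles 1..99 of a normal forecast distribution."""
    from scipy.stats import norm

    sd = max(float(sd), 0.0)
    return point + sd * norm.ppf(CENTILES / 100.0)
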