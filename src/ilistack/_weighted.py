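"""Weighted median and weighted percentiles for probabilistic forecasts.

The weighted median follows the double-inequality rule used for the
empirical-Bayes point forecast: after ranking the sample values, it is the
smallest value f_k such that the total weight strictly below it and the
total weight strictly above it are each at most half the total weight.
"""

from __future__ import annotations

import numpy as np

__all__ = ["weighted_median", "weighted_percentiles"]


def weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    """Weighted median by the double-inequality rule.

    Returns the smallest ranked value ``f_k`` with
    ``sum(w_i, i<k) <= W/2`` and ``sum(w_i, i>k) <= W/2`` where ``W`` is the
    total weight.  With equal weights and odd sample size this is the
    ordinary sample median.
    """
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if values.ndim != 1 or values.shape != weights.shape:
        raise ValueError("values and weights must be 1-d arrays of equal length")
    if values.size == 0:
        raise ValueError("cannot take the weighted median of an empty sample")
    if np.any(weights < 0):
        raise ValueError("weights must be nonnegative")
    total = weights.sum()
    if total <= 0:
        raise ValueError("total weight must be positive")
    order = np.argsort(values, kind="stable")
    v = values[order]
    w = weights[order] / total
    cum = np.cumsum(w)
    below = cum - w          # weight strictly below rank k
    above = 1.0 - cum        # weight strictly above rank k
    eps = 1e-12              # guard against cumsum round-off at the boundary
    ok = (below <= 0.5 + eps) & (above <= 0.5 + eps)
    k = int(np.argmax(ok))   # first admissible rank (ok is contiguous)
    return float(v[k])


def weighted_percentiles(
    values: np.ndarray, weights: np.ndarray, percentiles: np.ndarray
) -> np.ndarray:
    """Weighted empirical percentiles (inverse-CDF convention).

    Percentile ``p`` is the smallest ranked value whose cumulative
    normalized weight reaches ``p/100``.  Output is nondecreasing in ``p``.
    """
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    p = np.atleast_1d(np.asarray(percentiles, dtype=float))
    if np.any((p < 0) | (p > 100)):
        raise ValueError("percentiles must lie in [0, 100]")
    total = weights.sum()
    if total <= 0:
        raise ValueError("total weight must be positive")
    order = np.argsort(values, kind="stable")
    v = values[order]
    cum = np.cumsum(weights[order]) / total
    idx = np.searchsorted(cum, p / 100.0, side="left")
    idx = np.clip(idx, 0, v.size - 1)
    return v[idx]
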