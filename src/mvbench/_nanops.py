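"""Vectorised pairwise statistics over matrices with missing entries.

All functions take a (G, n) float array where NaN marks a missing value
and return G x G arrays computed over the mutually observed coordinates
of each row pair. They are the shared backend for the masked distance
d*, the kNN-family imputers and the correlation-based imputers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["pairwise_sq_dists", "PairwiseStats", "pairwise_stats"]


def pairwise_sq_dists(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Sum of squared differences over mutually observed coordinates.

    Returns ``(ssd, count)`` where ``ssd[i, k]`` is
    ``sum_j (x[i, j] - x[k, j])**2`` over coordinates observed in both
    rows and ``count[i, k]`` the number of such coordinates.
    """
    obs = np.isfinite(x)
    z = np.where(obs, x, 0.0)
    m = obs.astype(float)
    z2 = z * z
    ssd = z2 @ m.T + m @ z2.T - 2.0 * (z @ z.T)
    np.maximum(ssd, 0.0, out=ssd)  # clip tiny negative round-off
    count = m @ m.T
    return ssd, count


@dataclass
class PairwiseStats:
    """Per-pair sufficient statistics over mutually observed coordinates.

    For pair (i, k): ``count`` mutual observations, ``r`` the Pearson
    correlation (NaN when count < min_overlap or either side is constant),
    ``slope``/``intercept`` the simple regression of row i on row k.
    """

    count: np.ndarray
    r: np.ndarray
    slope: np.ndarray
    intercept: np.ndarray


def pairwise_stats(x: np.ndarray, min_overlap: int = 3) -> PairwiseStats:
    obs = np.isfinite(x)
    z = np.where(obs, x, 0.0)
    m = obs.astype(float)
    z2 = z * z
    c = m @ m.T
    sx = z @ m.T          # sum of row-i values over mutual coords
    sy = sx.T             # sum of row-k values
    sxx = z2 @ m.T
    syy = sxx.T
    sxy = z @ z.T
    with np.errstate(invalid="ignore", divide="ignore"):
        cov_num = c * sxy - sx * sy           # c^2 * covariance
        varx_num = c * sxx - sx * sx          # c^2 * variance of row i
        vary_num = c * syy - sy * sy
        r = cov_num / np.sqrt(varx_num * vary_num)
        slope = cov_num / vary_num            # regress row i on row k
        intercept = (sx - slope * sy) / c
    bad = (c < min_overlap) | ~np.isfinite(r)
    r = np.where(bad, np.nan, r)
    slope = np.where(bad, np.nan, slope)
    intercept = np.where(bad, np.nan, intercept)
    np.fill_diagonal(r, np.nan)
    return PairwiseStats(count=c, r=r, slope=slope, intercept=intercept)
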