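"""Least-squares imputers in gene space, array space, and their blends.

``lsi_gene`` regresses the target gene on each of its best-correlated
neighbours and combines the per-neighbour predictions with weights that
diverge as |r| -> 1. ``lsi_array`` models the conditions as a
multivariate normal estimated from the complete genes and imputes by
the conditional expectation. ``lsi_combined`` mixes the two with a
global weight p; ``lsi_adaptive`` lets p vary with the strength of the
best available gene-space correlation (r_max), estimated per bin by
secondary masking.
"""

from __future__ import annotations

import numpy as np
from scipy import linalg

from .._nanops import pairwise_stats
from ..core import ValidationError
from ..masking import MaskedDataset
from .base import (
    ImputationResult,
    finalize_result,
    register_method,
    secondary_mask,
)

__all__ = [
    "lsi_gene_impute",
    "lsi_array_impute",
    "lsi_combined_impute",
    "lsi_adaptive_impute",
]

_EPS_WEIGHT = 1e-6
_RIDGE_ARRAY = 1e-8
_P_GRID = np.round(np.linspace(0.0, 1.0, 101), 2)


def _lsi_gene_raw(
    x: np.ndarray, mask: np.ndarray, big_k: int
) -> tuple[np.ndarray, np.ndarray]:
    """Gene-space estimates and per-entry r_max (0 when no candidate)."""
    obs = np.isfinite(x)
    stats = pairwise_stats(x, min_overlap=3)
    raw = np.full(len(mask), np.nan)
    rmax = np.zeros(len(mask))
    for idx, (g, j) in enumerate(mask):
        r_g = stats.r[g]
        cand = np.flatnonzero(obs[:, j] & np.isfinite(r_g))
        if len(cand) == 0:
            continue
        order = cand[np.lexsort((cand, -np.abs(r_g[cand])))][:big_k]
        r = r_g[order]
        pred = stats.intercept[g, order] + stats.slope[g, order] * x[order, j]
        r2 = r * r
        w = (r2 / (1.0 - r2 + _EPS_WEIGHT)) ** 2
        if w.sum() <= 0:
            continue
        raw[idx] = float(np.dot(w, pred) / w.sum())
        rmax[idx] = float(np.abs(r).max())
    return raw, rmax


@register_method("lsi_gene")
def lsi_gene_impute(data: MaskedDataset, K: int = 10) -> ImputationResult:
    """Correlation-weighted regression on the K best-correlated genes.

    Candidates must be observed at the target condition and share at
    least 3 observed coordinates with the target gene; constant
    neighbours (undefined r) are disqualified.
    """
    if K < 1:
        raise ValidationError("K must be >= 1")
    raw, _ = _lsi_gene_raw(data.masked_values(), data.mask, K)
    return finalize_result(data, raw, "lsi_gene", {"K": int(K)})


def _lsi_array_raw(x: np.ndarray, mask: np.ndarray) -> np.ndarray:
    n = x.shape[1]
    complete = np.flatnonzero(np.isfinite(x).all(axis=1))
    raw = np.full(len(mask), np.nan)
    if len(complete) < 2:
        return raw
    xc = x[complete]
    mu = xc.mean(axis=0)
    sigma = np.cov(xc, rowvar=False, ddof=1) + _RIDGE_ARRAY * np.eye(n)

    by_gene: dict[int, list[int]] = {}
    for idx, (g, j) in enumerate(mask):
        by_gene.setdefault(int(g), []).append(idx)
    # one conditional-expectation solve per incomplete gene
    for g, idxs in by_gene.items():
        o = np.isfinite(x[g])
        mis = np.flatnonzero(~o)
        if o.sum() == 0:
            est = mu[mis]
        else:
            obs_idx = np.flatnonzero(o)
            s_oo = sigma[np.ix_(obs_idx, obs_idx)]
            s_mo = sigma[np.ix_(mis, obs_idx)]
            try:
                coef = linalg.solve(s_oo, x[g, o] - mu[obs_idx], assume_a="pos")
            except linalg.LinAlgError:
                coef, *_ = np.linalg.lstsq(s_oo, x[g, o] - mu[obs_idx], rcond=None)
            est = mu[mis] + s_mo @ coef
        col_of = {int(c): q for q, c in enumerate(mis)}
        for idx in idxs:
            raw[idx] = est[col_of[int(mask[idx, 1])]]
    return raw


@register_method("lsi_array")
def lsi_array_impute(data: MaskedDataset) -> ImputationResult:
    """Multivariate-normal conditional expectation over conditions.

    Mean and covariance come from the complete genes only (single pass,
    small diagonal ridge); needs at least 2 complete genes, otherwise
    everything goes through the fallback chain.
    """
    raw = _lsi_array_raw(data.masked_values(), data.mask)
    return finalize_result(data, raw, "lsi_array")


def _combine(gene_est: np.ndarray, array_est: np.ndarray, p) -> np.ndarray:
    """p * gene + (1-p) * array, degrading to whichever side is defined."""
    p = np.asarray(p, dtype=float)
    out = p * gene_est + (1.0 - p) * array_est
    only_gene = np.isfinite(gene_est) & ~np.isfinite(array_est)
    only_array = ~np.isfinite(gene_est) & np.isfinite(array_est)
    out[only_gene] = gene_est[only_gene]
    out[only_array] = array_est[only_array]
    return out


def _grid_best_p(
    gene_est: np.ndarray, array_est: np.ndarray, truth: np.ndarray
) -> float:
    best_p, best_err = 0.0, np.inf
    for p in _P_GRID:
        est = _combine(gene_est, array_est, p)
        ok = np.isfinite(est)
        if not ok.any():
            continue
        err = float(np.sqrt(np.mean((est[ok] - truth[ok]) ** 2)))
        if err < best_err:
            best_p, best_err = float(p), err
    return best_p


def _combined_inputs(data: MaskedDataset, K: int):
    x = data.masked_values()
    gene_est, rmax = _lsi_gene_raw(x, data.mask, K)
    array_est = _lsi_array_raw(x, data.mask)
    return gene_est, rmax, array_est


def _secondary_estimates(
    data: MaskedDataset, K: int, cv_fraction: float, rng: np.random.Generator
):
    combined, sec = secondary_mask(data, cv_fraction, rng, min_entries=1)
    x2 = combined.masked_values()
    gene2, rmax2 = _lsi_gene_raw(x2, combined.mask, K)
    array2 = _lsi_array_raw(x2, combined.mask)
    return gene2[sec], rmax2[sec], array2[sec], combined.truth[sec]


@register_method("lsi_combined")
def lsi_combined_impute(
    data: MaskedDataset,
    p: float | str = "auto",
    K: int = 10,
    cv_fraction: float = 0.05,
    seed: int | None = None,
) -> ImputationResult:
    """Blend of gene-space and array-space estimates: p*gene + (1-p)*array.

    ``p="auto"`` grid-searches p in {0, 0.01, ..., 1} to minimise the
    error on secondarily masked observed entries.
    """
    if data.n_masked == 0:
        return finalize_result(data, np.empty(0), "lsi_combined", {"K": int(K)})
    gene_est, _, array_est = _combined_inputs(data, K)
    params: dict = {"K": int(K)}
    if p == "auto":
        rng = np.random.default_rng(data.seed if seed is None else seed)
        gene2, _, array2, truth2 = _secondary_estimates(data, K, cv_fraction, rng)
        p = _grid_best_p(gene2, array2, truth2)
        params["p_auto"] = True
    p = float(p)
    if not 0.0 <= p <= 1.0:
        raise ValidationError("p must be in [0, 1]")
    params["p"] = p
    raw = _combine(gene_est, array_est, p)
    return finalize_result(data, raw, "lsi_combined", params)


@register_method("lsi_adaptive")
def lsi_adaptive_impute(
    data: MaskedDataset,
    bins: int = 10,
    K: int = 10,
    cv_fraction: float = 0.05,
    seed: int | None = None,
) -> ImputationResult:
    """As lsi_combined but p varies per entry with r_max.

    Entries are bucketed by r_max into equal-width bins on [0, 1]; each
    bin's p comes from the same secondary-masking grid search, and bins
    with fewer than 20 secondary entries inherit the global p.
    """
    if bins < 1:
        raise ValidationError("bins must be >= 1")
    if data.n_masked == 0:
        return finalize_result(
            data, np.empty(0), "lsi_adaptive", {"K": int(K), "bins": int(bins)}
        )
    gene_est, rmax, array_est = _combined_inputs(data, K)
    rng = np.random.default_rng(data.seed if seed is None else seed)
    gene2, rmax2, array2, truth2 = _secondary_estimates(data, K, cv_fraction, rng)
    p_global = _grid_best_p(gene2, array2, truth2)

    def bin_of(r: np.ndarray) -> np.ndarray:
        return np.clip((r * bins).astype(int), 0, bins - 1)

    p_bins = np.full(bins, p_global)
    b2 = bin_of(rmax2)
    for b in range(bins):
        in_bin = b2 == b
        if int(in_bin.sum()) >= 20:
            p_bins[b] = _grid_best_p(gene2[in_bin], array2[in_bin], truth2[in_bin])

    p_entry = p_bins[bin_of(rmax)] if data.n_masked else np.empty(0)
    raw = _combine(gene_est, array_est, p_entry)
    params = {
        "K": int(K),
        "bins": int(bins),
        "p_global": float(p_global),
        "p_bins": [float(v) for v in p_bins],
    }
    return finalize_result(data, raw, "lsi_adaptive", params)
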