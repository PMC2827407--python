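"""Neighbour-based imputers: row mean, kNN, sequential kNN, LLSI.

kNN follows the KNNimpute convention: for a masked entry (g, j) the
candidate donors are genes observed at condition j that share at least
one observed coordinate with g; distances are the masked normalized
Euclidean d* and the k nearest donors contribute an inverse-distance
weighted mean of their j-values.
"""

from __future__ import annotations

import numpy as np

from .._nanops import pairwise_sq_dists
from ..core import ValidationError
from ..masking import MaskedDataset
from .base import (
    ImputationResult,
    finalize_result,
    register_method,
    secondary_mask,
)

__all__ = [
    "row_mean_impute",
    "knn_impute",
    "select_k_opt",
    "sknn_impute",
    "llsi_impute",
]

_EPS_KNN = 1e-9


@register_method("row_mean")
def row_mean_impute(data: MaskedDataset) -> ImputationResult:
    """Estimate each masked entry by the mean of its gene's observed values."""
    x = data.masked_values()
    row_means = np.full(x.shape[0], np.nan)
    ok = np.isfinite(x).any(axis=1)
    if ok.any():
        row_means[ok] = np.nanmean(x[ok], axis=1)
    raw = row_means[data.mask[:, 0]] if data.n_masked else np.empty(0)
    return finalize_result(data, raw, "row_mean")


def _dstar_matrix(x: np.ndarray) -> np.ndarray:
    """All-pairs masked distance d*; inf where no shared coordinate."""
    n = x.shape[1]
    ssd, count = pairwise_sq_dists(x)
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.sqrt(n / count * ssd)
    d[count == 0] = np.inf
    return d


def _knn_raw(x: np.ndarray, mask: np.ndarray, k: int) -> np.ndarray:
    obs = np.isfinite(x)
    d = _dstar_matrix(x)
    np.fill_diagonal(d, np.inf)  # a gene is not its own donor
    raw = np.full(len(mask), np.nan)
    order_cache: dict[int, np.ndarray] = {}
    for idx, (g, j) in enumerate(mask):
        if g not in order_cache:
            order_cache[g] = np.argsort(d[g], kind="stable")
        order = order_cache[g]
        cand = order[obs[order, j] & np.isfinite(d[g, order])]
        if len(cand) == 0:
            continue
        top = cand[:k]
        w = 1.0 / (d[g, top] + _EPS_KNN)
        raw[idx] = float(np.dot(w, x[top, j]) / w.sum())
    return raw


@register_method("knn")
def knn_impute(data: MaskedDataset, k: int = 10) -> ImputationResult:
    """Weighted k-nearest-neighbour imputation (inverse d* weights)."""
    if k < 1:
        raise ValidationError("k must be >= 1")
    raw = _knn_raw(data.masked_values(), data.mask, k)
    return finalize_result(data, raw, "knn", {"k": int(k)})


def select_k_opt(
    data: MaskedDataset,
    candidates: list[int],
    cv_fraction: float = 0.05,
    seed: int | None = None,
) -> int:
    """Choose the k with minimal error on secondarily masked observed entries.

    Ties resolve to the smallest k; deterministic given the seed (the
    dataset's own seed when none is given).
    """
    if not candidates:
        raise ValidationError("candidate list must be non-empty")
    rng = np.random.default_rng(data.seed if seed is None else seed)
    combined, sec = secondary_mask(data, cv_fraction, rng)
    truth = combined.truth[sec]
    best_k, best_err = None, np.inf
    for k in sorted(int(k) for k in candidates):
        raw = _knn_raw(combined.masked_values(), combined.mask, k)
        res = finalize_result(combined, raw, "knn")
        err = float(np.sqrt(np.mean((res.estimates[sec] - truth) ** 2)))
        if err < best_err:
            best_k, best_err = k, err
    return int(best_k)


@register_method("sknn")
def sknn_impute(data: MaskedDataset, k: int = 10) -> ImputationResult:
    """Sequential kNN: impute genes in order of ascending missing count.

    Complete genes form the initial donor pool; each imputed gene joins
    the pool and can donate to later genes. With no complete gene the
    least-missing gene is seeded by its row mean (recorded in params).
    """
    if k < 1:
        raise ValidationError("k must be >= 1")
    x = data.masked_values()
    g_count, n = x.shape
    miss_count = np.isnan(x).sum(axis=1)
    params: dict = {"k": int(k)}

    pool = list(np.flatnonzero(miss_count == 0))
    order = [int(i) for i in np.lexsort((np.arange(g_count), miss_count))
             if miss_count[i] > 0]
    if not pool and order:
        seed_gene = order.pop(0)
        row = x[seed_gene]
        fill = np.nanmean(row) if np.isfinite(row).any() else np.nanmean(x)
        if not np.isfinite(fill):
            fill = 0.0
        x[seed_gene, np.isnan(row)] = fill
        pool.append(seed_gene)
        params["seeded_by_row_mean"] = True

    for g in order:
        row = x[g]
        obs = np.isfinite(row)
        n_obs = int(obs.sum())
        mis = np.flatnonzero(~obs)
        if n_obs == 0 or not pool:
            continue  # left NaN; fallback chain handles it
        pool_arr = np.asarray(pool)
        diff = x[pool_arr][:, obs] - row[obs]
        d = np.sqrt(n / n_obs * np.sum(diff * diff, axis=1))
        nearest = np.argsort(d, kind="stable")[:k]
        w = 1.0 / (d[nearest] + _EPS_KNN)
        est = (w @ x[pool_arr[nearest]][:, mis]) / w.sum()
        x[g, mis] = est
        pool.append(g)

    raw = (
        x[data.mask[:, 0], data.mask[:, 1]] if data.n_masked else np.empty(0)
    )
    return finalize_result(data, raw, "sknn", params)


def _llsi_raw(x: np.ndarray, mask: np.ndarray, k: int) -> np.ndarray:
    obs = np.isfinite(x)
    n = x.shape[1]
    raw = np.full(len(mask), np.nan)
    by_gene: dict[int, list[int]] = {}
    for idx, (g, j) in enumerate(mask):
        by_gene.setdefault(int(g), []).append(idx)
    for g, idxs in by_gene.items():
        o = obs[g]
        mis = ~o
        n_obs = int(o.sum())
        if n_obs == 0:
            continue
        # neighbours must be observed on the target gene's full support
        qualified = np.flatnonzero(obs[:, o | mis].all(axis=1))
        qualified = qualified[qualified != g]
        if len(qualified) == 0:
            continue
        diff = x[qualified][:, o] - x[g, o]
        d = np.sqrt(n / n_obs * np.sum(diff * diff, axis=1))
        nb = qualified[np.argsort(d, kind="stable")[:k]]
        a = x[nb][:, o]           # k x |O|
        b = x[nb][:, mis]         # k x |M|
        w = x[g, o]
        coef, *_ = np.linalg.lstsq(a.T, w, rcond=None)
        est = b.T @ coef
        mis_pos = np.flatnonzero(mis)
        col_of = {int(c): q for q, c in enumerate(mis_pos)}
        for idx in idxs:
            raw[idx] = est[col_of[int(mask[idx, 1])]]
    return raw


@register_method("llsi")
def llsi_impute(
    data: MaskedDataset,
    k: int | str = 10,
    cv_fraction: float = 0.05,
    seed: int | None = None,
) -> ImputationResult:
    """Local least squares: express a gene as a combination of its nearest
    neighbours over its observed coordinates, then extrapolate to the
    missing ones. ``k="auto"`` picks k from {5, 10, 15, 20} by secondary
    masking.
    """
    params: dict = {}
    if k == "auto" and data.n_masked == 0:
        k = 10
    if k == "auto":
        rng = np.random.default_rng(data.seed if seed is None else seed)
        combined, sec = secondary_mask(data, cv_fraction, rng, min_entries=1)
        truth = combined.truth[sec]
        best_k, best_err = None, np.inf
        for kk in (5, 10, 15, 20):
            raw = _llsi_raw(combined.masked_values(), combined.mask, kk)
            res = finalize_result(combined, raw, "llsi")
            err = float(np.sqrt(np.mean((res.estimates[sec] - truth) ** 2)))
            if err < best_err:
                best_k, best_err = kk, err
        k = best_k
        params["k_auto"] = True
    if int(k) < 1:
        raise ValidationError("k must be >= 1")
    params["k"] = int(k)
    raw = _llsi_raw(data.masked_values(), data.mask, int(k))
    return finalize_result(data, raw, "llsi", params)
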