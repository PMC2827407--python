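"""Expectation-maximisation imputers for multivariate normal data.

``em_array`` fits a multivariate normal over the n conditions with
genes as observations: the E-step replaces each gene's missing
coordinates by their conditional expectation (and accumulates the
conditional covariance), the M-step re-estimates the mean vector and
covariance including that correction. The observed-data log-likelihood
is non-decreasing across iterations.

``em_gene`` runs the same machinery in gene space, restricted per
incomplete gene to a small system of the gene plus its K most
correlated neighbours (variables = genes, observations = conditions),
with a ridge to keep the rank-deficient small-sample covariance
invertible.
"""

from __future__ import annotations

import numpy as np
from scipy import linalg

from .._nanops import pairwise_stats
from ..core import ValidationError
from ..masking import MaskedDataset
from .base import ImputationResult, finalize_result, register_method

__all__ = ["em_mvn", "em_array_impute", "em_gene_impute"]

_LOG2PI = float(np.log(2.0 * np.pi))


def _solve_spd(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    try:
        return linalg.solve(a, b, assume_a="pos")
    except linalg.LinAlgError:
        sol, *_ = np.linalg.lstsq(a, b, rcond=None)
        return sol


def em_mvn(
    x: np.ndarray,
    tol: float = 1e-6,
    max_iter: int = 300,
    ridge: float = 0.0,
):
    """EM for a d-variate normal from an (N, d) sample with NaN gaps.

    Returns ``(completed, mu, sigma, n_iter, converged, loglik_trace)``.
    Missing cells are initialised by their row's observed mean (falling
    back to the global mean); maximum-likelihood moments are used
    throughout. ``loglik_trace[t]`` is the observed-data log-likelihood
    of the parameters entering iteration t; with ridge = 0 it is
    non-decreasing.
    """
    x = np.asarray(x, dtype=float)
    n_rows, d = x.shape
    miss = ~np.isfinite(x)
    global_mean = float(np.nanmean(x)) if np.isfinite(x).any() else 0.0

    xc = x.copy()
    for i in np.flatnonzero(miss.any(axis=1)):
        row = x[i]
        fill = np.nanmean(row) if np.isfinite(row).any() else global_mean
        xc[i, miss[i]] = fill

    mu = xc.mean(axis=0)
    dev = xc - mu
    sigma = (dev.T @ dev) / n_rows + ridge * np.eye(d)

    # group rows by missing pattern so each pattern is solved once per pass
    grouped: dict[tuple, list[int]] = {}
    for i in range(n_rows):
        grouped.setdefault(tuple(np.flatnonzero(miss[i])), []).append(i)
    patterns = [
        (np.asarray(k, dtype=int),
         np.setdiff1d(np.arange(d), np.asarray(k, dtype=int)),
         np.asarray(v))
        for k, v in grouped.items()
    ]

    loglik_trace: list[float] = []
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        corr = np.zeros((d, d))
        loglik = 0.0
        for mis, o, rows in patterns:
            if len(o):
                s_oo = sigma[np.ix_(o, o)]
                resid = x[np.ix_(rows, o)] - mu[o]
                sign, logdet = np.linalg.slogdet(s_oo)
                sol = _solve_spd(s_oo, resid.T)  # |O| x n_rows
                maha = np.einsum("ij,ij->j", resid.T, sol)
                loglik += -0.5 * (
                    len(rows) * (len(o) * _LOG2PI + logdet) + maha.sum()
                )
            if len(mis) == 0:
                continue
            if len(o) == 0:
                xc[np.ix_(rows, mis)] = mu[mis]
                corr[np.ix_(mis, mis)] += len(rows) * sigma[np.ix_(mis, mis)]
                continue
            s_mo = sigma[np.ix_(mis, o)]
            k = _solve_spd(sigma[np.ix_(o, o)], s_mo.T).T  # |M| x |O|
            xc[np.ix_(rows, mis)] = mu[mis] + resid @ k.T
            cond_cov = sigma[np.ix_(mis, mis)] - k @ s_mo.T
            corr[np.ix_(mis, mis)] += len(rows) * cond_cov
        loglik_trace.append(float(loglik))

        mu_new = xc.mean(axis=0)
        dev = xc - mu_new
        sigma_new = (dev.T @ dev + corr) / n_rows + ridge * np.eye(d)

        scale = max(np.abs(mu).max(), np.abs(sigma).max(), 1e-12)
        delta = max(
            np.abs(mu_new - mu).max(), np.abs(sigma_new - sigma).max()
        ) / scale
        mu, sigma = mu_new, sigma_new
        if delta < tol:
            converged = True
            break

    return xc, mu, sigma, n_iter, converged, loglik_trace


@register_method("em_array")
def em_array_impute(
    data: MaskedDataset, tol: float = 1e-6, max_iter: int = 300
) -> ImputationResult:
    """EM imputation of a multivariate normal over the conditions."""
    if data.reference.n_conditions > 64:
        raise ValidationError("em_array requires n <= 64 conditions")
    x = data.masked_values()
    xc, mu, sigma, n_iter, converged, trace = em_mvn(
        x, tol=tol, max_iter=max_iter, ridge=0.0
    )
    raw = (
        xc[data.mask[:, 0], data.mask[:, 1]] if data.n_masked else np.empty(0)
    )
    params = {
        "tol": tol,
        "iterations": int(n_iter),
        "converged": bool(converged),
        "loglik_trace": [float(v) for v in trace],
    }
    return finalize_result(data, raw, "em_array", params)


@register_method("em_gene")
def em_gene_impute(
    data: MaskedDataset,
    K: int = 10,
    tol: float = 1e-4,
    max_iter: int = 100,
) -> ImputationResult:
    """Neighbourhood EM in gene space.

    For each incomplete gene the EM runs on the small system of the
    gene plus its K most |r|-correlated neighbours (>= 3 mutually
    observed coordinates required), with variables = genes and
    observations = conditions (ridge 1e-6). Genes with no qualified
    neighbour go through the fallback chain. The default tolerance is
    looser than em_array's: with fewer observations (conditions) than
    variables the ridge-regularised covariance drifts slowly and a
    1e-6 relative criterion is rarely reachable.
    """
    if K < 1:
        raise ValidationError("K must be >= 1")
    x = data.masked_values()
    stats = pairwise_stats(x, min_overlap=3)
    raw = np.full(data.n_masked, np.nan)
    by_gene: dict[int, list[int]] = {}
    for idx, (g, j) in enumerate(data.mask):
        by_gene.setdefault(int(g), []).append(idx)
    n_converged = 0
    for g, idxs in by_gene.items():
        r_g = stats.r[g]
        cand = np.flatnonzero(np.isfinite(r_g))
        if len(cand) == 0:
            continue
        nbrs = cand[np.lexsort((cand, -np.abs(r_g[cand])))][:K]
        sub = x[np.concatenate(([g], nbrs))].T  # n x (K+1): rows = conditions
        xc, *_rest, converged, _trace = em_mvn(
            sub, tol=tol, max_iter=max_iter, ridge=1e-6
        )
        n_converged += bool(converged)
        for idx in idxs:
            raw[idx] = xc[int(data.mask[idx, 1]), 0]
    params = {"K": int(K), "tol": tol, "n_converged_systems": int(n_converged)}
    return finalize_result(data, raw, "em_gene", params)
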