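"""Imputation accuracy scores: RMSE, estimate/truth correlation, win rates."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import ValidationError
from .impute.base import ImputationResult
from .masking import MaskedDataset

__all__ = [
    "AccuracyRecord",
    "rmse",
    "predicted_true_correlation",
    "pairwise_win_matrix",
]


@dataclass
class AccuracyRecord:
    """One (method, tau, replicate, scope) accuracy outcome."""

    method: str
    tau: float
    replicate: int
    scope: str
    rmse: float
    r: float | None
    n_entries: int


def rmse(
    result: ImputationResult, data: MaskedDataset, normalized: bool = False
) -> float:
    """Root mean square error between estimates and held-out true values.

    Unnormalised, on the log2-ratio scale. ``normalized=True`` divides
    by the standard deviation of the truths (for cross-literature
    comparison only).
    """
    if data.n_masked == 0:
        raise ValidationError("rmse is undefined for an empty mask")
    if len(result.estimates) != data.n_masked:
        raise ValidationError("estimates do not cover the mask")
    err = result.estimates - data.truth
    value = float(np.sqrt(np.mean(err * err)))
    if normalized:
        sd = float(np.std(data.truth))
        if sd == 0:
            raise ValidationError("normalized rmse undefined: constant truths")
        value /= sd
    return value


def predicted_true_correlation(
    result: ImputationResult, data: MaskedDataset
) -> float | None:
    """Pearson correlation between estimates and truths; None when
    either side has zero variance."""
    if data.n_masked < 3:
        raise ValidationError("correlation needs at least 3 masked entries")
    est, truth = result.estimates, data.truth
    if np.std(est) == 0 or np.std(truth) == 0:
        return None
    return float(sps.pearsonr(est, truth)[0])


def pairwise_win_matrix(records: pd.DataFrame) -> pd.DataFrame:
    """Percentage of simulations where the row method beats the column one.

    ``records`` must hold one row per (method, simulation) with columns
    ``method``, ``rmse`` and simulation keys (any of ``dataset``,
    ``scope``, ``tau``, ``replicate`` that are present). All methods
    must cover the same simulations; exact RMSE ties count 0.5 to each
    side, so cell(A, B) + cell(B, A) = 100. The diagonal is NaN.
    """
    required = {"method", "rmse"}
    if not required.issubset(records.columns):
        raise ValidationError("records need 'method' and 'rmse' columns")
    keys = [c for c in ("dataset", "scope", "tau", "replicate")
            if c in records.columns]
    if not keys:
        raise ValidationError("records need at least one simulation key column")
    wide = records.pivot_table(index=keys, columns="method", values="rmse")
    if wide.isna().any().any():
        raise ValidationError("methods were not evaluated on identical simulations")
    methods = list(wide.columns)
    if len(methods) < 2:
        raise ValidationError("need at least two methods")
    n = len(wide)
    out = pd.DataFrame(np.nan, index=methods, columns=methods)
    for a in methods:
        for b in methods:
            if a == b:
                continue
            wins = (wide[a] < wide[b]).sum() + 0.5 * (wide[a] == wide[b]).sum()
            out.loc[a, b] = 100.0 * wins / n
    return out
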