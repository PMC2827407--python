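"""Shared imputation plumbing: result type, method registry, fallbacks.

Every imputer estimates the masked entries of a :class:`MaskedDataset`
and leaves all observed entries untouched. Where a method cannot produce
an estimate (no qualified neighbour, empty row, ...), a shared fallback
chain fills the gap and its usage is recorded:

    method estimate -> gene observed mean -> condition observed mean
                    -> global observed mean -> 0
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from ..core import ExpressionMatrix, ValidationError
from ..masking import MaskedDataset, round_half_away

__all__ = [
    "ImputationResult",
    "MethodSpec",
    "METHOD_NAMES",
    "register_method",
    "get_method",
    "impute",
    "finalize_result",
    "secondary_mask",
]

#: registry of imputer callables, keyed by method name
_REGISTRY: dict[str, Callable[..., "ImputationResult"]] = {}

METHOD_NAMES = frozenset(
    {
        "row_mean",
        "knn",
        "sknn",
        "llsi",
        "lsi_gene",
        "lsi_array",
        "lsi_combined",
        "lsi_adaptive",
        "em_gene",
        "em_array",
        "bpca",  # reserved plugin hook; no built-in implementation
    }
)


@dataclass
class ImputationResult:
    """A completed matrix plus the per-masked-entry estimates.

    ``estimates[i]`` corresponds to mask row ``i`` of the input dataset.
    ``params`` records hyperparameters, iteration counts and fallback
    usage for auditability.
    """

    completed: ExpressionMatrix
    estimates: np.ndarray = field(repr=False)
    method: str = ""
    params: dict = field(default_factory=dict)


@dataclass
class MethodSpec:
    """A named imputation method plus its hyperparameters."""

    name: str
    hyperparameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.name not in METHOD_NAMES:
            raise ValidationError(f"unknown imputation method {self.name!r}")


def register_method(name: str):
    def deco(fn):
        _REGISTRY[name] = fn
        return fn

    return deco


def get_method(name: str) -> Callable[..., ImputationResult]:
    if name not in METHOD_NAMES:
        raise ValidationError(f"unknown imputation method {name!r}")
    if name not in _REGISTRY:
        raise NotImplementedError(
            f"method {name!r} is a plugin hook with no built-in implementation"
        )
    return _REGISTRY[name]


def impute(spec: MethodSpec, data: MaskedDataset) -> ImputationResult:
    """Dispatch to the named method with its hyperparameters."""
    fn = get_method(spec.name)
    return fn(data, **spec.hyperparameters)


# ----------------------------------------------------------------------
def finalize_result(
    data: MaskedDataset,
    raw_estimates: np.ndarray,
    method: str,
    params: dict | None = None,
) -> ImputationResult:
    """Apply the fallback chain to undefined estimates and build the result.

    ``raw_estimates`` is aligned with ``data.mask``; NaN marks an entry
    the method could not estimate. The completed matrix equals the
    reference on every unmasked entry by construction.
    """
    params = dict(params or {})
    est = np.asarray(raw_estimates, dtype=float).copy()
    if est.shape != (data.n_masked,):
        raise ValidationError("estimates must align with the mask")

    x = data.masked_values()
    counts = {"gene_mean": 0, "condition_mean": 0, "global_mean": 0, "zero": 0}
    todo = np.flatnonzero(~np.isfinite(est))
    if len(todo):
        for idx in todo:
            i, j = data.mask[idx]
            gm = np.nanmean(x[i]) if np.isfinite(x[i]).any() else np.nan
            if np.isfinite(gm):
                est[idx] = gm
                counts["gene_mean"] += 1
                continue
            cm = np.nanmean(x[:, j]) if np.isfinite(x[:, j]).any() else np.nan
            if np.isfinite(cm):
                est[idx] = cm
                counts["condition_mean"] += 1
                continue
            gl = np.nanmean(x) if np.isfinite(x).any() else np.nan
            if np.isfinite(gl):
                est[idx] = gl
                counts["global_mean"] += 1
            else:
                est[idx] = 0.0
                counts["zero"] += 1

    completed_values = data.reference.values.copy()
    if data.n_masked:
        completed_values[data.mask[:, 0], data.mask[:, 1]] = est
    completed = ExpressionMatrix(
        list(data.reference.gene_ids),
        list(data.reference.condition_ids),
        completed_values,
    )
    params["fallbacks"] = counts
    params["n_fallback"] = int(sum(counts.values()))
    return ImputationResult(
        completed=completed, estimates=est, method=method, params=params
    )


def secondary_mask(
    data: MaskedDataset,
    cv_fraction: float,
    rng: np.random.Generator,
    min_entries: int = 10,
) -> tuple[MaskedDataset, slice]:
    """Hide a fraction of the OBSERVED entries for internal cross-validation.

    Returns a dataset whose mask is the primary mask followed by the
    secondary entries, and the slice selecting the secondary rows in
    that combined mask (and in any aligned estimates array).
    """
    if not 0 < cv_fraction < 1:
        raise ValidationError("cv_fraction must be in (0, 1)")
    g, n = data.reference.shape
    observed_flat = np.setdiff1d(
        np.arange(g * n), data.mask[:, 0] * n + data.mask[:, 1], assume_unique=False
    )
    count = round_half_away(cv_fraction * len(observed_flat))
    if count < min_entries:
        raise ValidationError(
            f"cv_fraction={cv_fraction} would mask only {count} entries (< {min_entries})"
        )
    chosen = rng.choice(observed_flat, size=count, replace=False)
    sec = np.column_stack(np.divmod(np.sort(chosen), n))
    mask = np.vstack([data.mask, sec]) if data.n_masked else sec
    truth = data.reference.values[mask[:, 0], mask[:, 1]]
    combined = MaskedDataset(
        data.reference,
        mask,
        truth,
        tau=100.0 * len(mask) / (g * n),
        scope=data.scope,
        seed=data.seed,
    )
    return combined, slice(data.n_masked, data.n_masked + count)
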