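"""Simulate missing values at a controlled rate tau.

A mask hides ``round(tau/100 * |eligible|)`` entries of a complete
reference matrix, drawn uniformly without replacement. The eligible set
is either every entry (scope ``all``) or the fraction of entries with
the largest absolute values (scope ``extreme``) — biologically the
strongest up/down-regulations and the hardest to impute. At tau = 10%
of a 1% extreme set, 0.1% of all entries are masked.

A gene may lose any number of its values, including all of them; no
minimum-observed guard is applied. Robustness at high tau is delegated
to the imputers' fallback chain.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core import ExpressionMatrix, ValidationError

__all__ = [
    "MaskedDataset",
    "simulate_mask",
    "extreme_value_set",
    "simulate_extreme_mask",
    "write_mask",
    "spawn_rng",
    "round_half_away",
]


def round_half_away(x: float) -> int:
    """Round with halves away from zero (unbiased over a regular tau grid)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def spawn_rng(master_seed: int, *keys: int) -> np.random.Generator:
    """Derive an independent substream from a master seed and integer keys.

    Counter-based: any single (tau, replicate, ...) cell is reproducible
    in isolation from the master seed alone.
    """
    return np.random.default_rng(
        np.random.SeedSequence([int(master_seed)] + [int(k) for k in keys])
    )


@dataclass
class MaskedDataset:
    """A complete reference matrix plus a simulated missing-entry mask.

    ``mask`` is an (M, 2) integer array of (gene index, condition index)
    pairs, ``truth`` the parallel array of erased true values.
    """

    reference: ExpressionMatrix
    mask: np.ndarray = field(repr=False)
    truth: np.ndarray = field(repr=False)
    tau: float
    scope: str = "all"
    seed: int = 0

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=int).reshape(-1, 2)
        self.truth = np.asarray(self.truth, dtype=float).reshape(-1)
        if not self.reference.is_complete:
            raise ValidationError("reference matrix must be complete")
        if self.scope not in ("all", "extreme"):
            raise ValidationError(f"unknown scope {self.scope!r}")
        if len(self.mask) != len(self.truth):
            raise ValidationError("truth must cover exactly the mask")
        if len(self.mask):
            g, n = self.reference.shape
            if (
                self.mask.min() < 0
                or self.mask[:, 0].max() >= g
                or self.mask[:, 1].max() >= n
            ):
                raise ValidationError("mask positions out of bounds")
            flat = self.mask[:, 0] * n + self.mask[:, 1]
            if len(np.unique(flat)) != len(flat):
                raise ValidationError("mask positions must be unique")

    @property
    def n_masked(self) -> int:
        return len(self.mask)

    def masked_values(self) -> np.ndarray:
        """The reference grid with masked entries set to NaN."""
        out = self.reference.values.copy()
        if len(self.mask):
            out[self.mask[:, 0], self.mask[:, 1]] = np.nan
        return out

    def masked_matrix(self) -> ExpressionMatrix:
        return ExpressionMatrix(
            list(self.reference.gene_ids),
            list(self.reference.condition_ids),
            self.masked_values(),
        )

    def mask_set(self) -> set[tuple[int, int]]:
        return {(int(i), int(j)) for i, j in self.mask}


def simulate_mask(ref: ExpressionMatrix, tau: float, seed: int) -> MaskedDataset:
    """Mask ``round(tau/100 * G*n)`` entries uniformly without replacement."""
    if not ref.is_complete:
        raise ValidationError("reference matrix must be complete")
    if tau < 0 or tau > 50:
        raise ValidationError("tau must be in [0, 50] percent")
    g, n = ref.shape
    count = round_half_away(tau / 100.0 * g * n)
    rng = np.random.default_rng(seed)
    flat = rng.choice(g * n, size=count, replace=False)
    mask = np.column_stack(np.divmod(flat, n)) if count else np.empty((0, 2), int)
    truth = ref.values[mask[:, 0], mask[:, 1]] if count else np.empty(0)
    return MaskedDataset(ref, mask, truth, tau=tau, scope="all", seed=seed)


def extreme_value_set(
    ref: ExpressionMatrix, fraction: float = 0.01
) -> np.ndarray:
    """The ``round(fraction * G*n)`` entries with largest absolute value.

    Ties at the cutoff are broken by (gene index, condition index)
    lexicographic order. Returns an (E, 2) index array in that order.
    """
    if not ref.is_complete:
        raise ValidationError("reference matrix must be complete")
    if not 0 < fraction < 1:
        raise ValidationError("fraction must be in (0, 1)")
    g, n = ref.shape
    count = round_half_away(fraction * g * n)
    if count == 0:
        raise ValidationError("fraction yields an empty extreme set")
    flat_abs = np.abs(ref.values).ravel()
    # stable sort on flat index after primary key -|value| implements the
    # lexicographic tie-break
    order = np.lexsort((np.arange(g * n), -flat_abs))
    chosen = np.sort(order[:count])
    return np.column_stack(np.divmod(chosen, n))


def simulate_extreme_mask(
    ref: ExpressionMatrix, tau: float, fraction: float = 0.01, seed: int = 0
) -> MaskedDataset:
    """Mask ``round(tau/100 * |extreme set|)`` entries of the extreme set."""
    if tau < 0 or tau > 100:
        raise ValidationError("tau must be in [0, 100] percent")
    extreme = extreme_value_set(ref, fraction)
    count = round_half_away(tau / 100.0 * len(extreme))
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(extreme), size=count, replace=False)
    mask = extreme[np.sort(idx)]
    truth = ref.values[mask[:, 0], mask[:, 1]]
    return MaskedDataset(ref, mask, truth, tau=tau, scope="extreme", seed=seed)


def write_mask(data: MaskedDataset, path) -> None:
    """Serialize a mask for audit: gene_id, condition_id, true value."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("gene_id\tcondition_id\ttrue_value\n")
        for (i, j), v in zip(data.mask, data.truth):
            fh.write(
                f"{data.reference.gene_ids[i]}\t"
                f"{data.reference.condition_ids[j]}\t{format(v, '.17g')}\n"
            )
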