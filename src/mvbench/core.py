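"""Core container for gene-expression matrices.

Expression data are stored as a genes x conditions grid of log2 ratios.
Missing values (filtered or corrupted microarray spots) are represented
as NaN in the float grid and are first-class throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ExpressionMatrix", "ValidationError", "ParseError"]


class ValidationError(ValueError):
    """A domain object violates one of its invariants."""


class ParseError(ValueError):
    """An input file could not be parsed; the message names the line."""


@dataclass
class ExpressionMatrix:
    """A genes x conditions matrix of log2 expression ratios.

    Parameters
    ----------
    gene_ids : list of str
        Unique row identifiers (genes), order-preserving.
    condition_ids : list of str
        Unique column identifiers (experimental conditions).
    values : ndarray of shape (G, n)
        Log2-ratio values; NaN marks a missing value. Every non-missing
        entry must be finite.
    """

    gene_ids: list[str]
    condition_ids: list[str]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.gene_ids = list(self.gene_ids)
        self.condition_ids = list(self.condition_ids)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("values must be a 2-D grid")
        g, n = self.values.shape
        if g < 2 or n < 2:
            raise ValidationError(
                f"matrix must have >= 2 genes and >= 2 conditions, got {g} x {n}"
            )
        if len(self.gene_ids) != g or len(self.condition_ids) != n:
            raise ValidationError("identifier lists do not match grid dimensions")
        if len(set(self.gene_ids)) != g:
            raise ValidationError("duplicate gene identifiers")
        if len(set(self.condition_ids)) != n:
            raise ValidationError("duplicate condition identifiers")
        if any(not i for i in self.gene_ids) or any(not i for i in self.condition_ids):
            raise ValidationError("empty identifiers are not allowed")
        if np.isinf(self.values).any():
            raise ValidationError("non-missing values must be finite")
        if np.isnan(self.values).all():
            raise ValidationError("matrix contains no observed values")

    # ------------------------------------------------------------------
    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_conditions(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def missing(self) -> np.ndarray:
        """Boolean (G, n) grid, True where the value is missing."""
        return np.isnan(self.values)

    @property
    def observed(self) -> np.ndarray:
        """Boolean (G, n) grid, True where the value is observed."""
        return ~np.isnan(self.values)

    @property
    def n_missing(self) -> int:
        return int(np.isnan(self.values).sum())

    @property
    def is_complete(self) -> bool:
        return self.n_missing == 0

    # ------------------------------------------------------------------
    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(
            list(self.gene_ids), list(self.condition_ids), self.values.copy()
        )

    def take_genes(self, index: np.ndarray) -> "ExpressionMatrix":
        """Row subset by integer index (order given by ``index``)."""
        index = np.asarray(index, dtype=int)
        return ExpressionMatrix(
            [self.gene_ids[i] for i in index],
            list(self.condition_ids),
            self.values[index, :].copy(),
        )

    def take_conditions(self, index: np.ndarray) -> "ExpressionMatrix":
        """Column subset by integer index."""
        index = np.asarray(index, dtype=int)
        return ExpressionMatrix(
            list(self.gene_ids),
            [self.condition_ids[j] for j in index],
            self.values[:, index].copy(),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ExpressionMatrix):
            return NotImplemented
        return (
            self.gene_ids == other.gene_ids
            and self.condition_ids == other.condition_ids
            and np.array_equal(self.values, other.values, equal_nan=True)
        )
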