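"""Read, write, filter and subsample tab-delimited expression matrices.

Two dialects are supported: ``plain`` (header row of condition names,
first column of gene identifiers) and ``pcl`` (Stanford PCL: an optional
GWEIGHT column and an optional EWEIGHT row, both ignored on input).
Missing values may be encoded as an empty field, ``NA``, ``nan`` or
``NaN``; they are always written back as ``NA``.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np

from .core import ExpressionMatrix, ParseError, ValidationError

__all__ = [
    "read_matrix",
    "write_matrix",
    "build_reference_matrix",
    "subsample_genes",
]

MISSING_TOKENS = {"", "NA", "nan", "NaN"}


def _parse_value(token: str, path, line_no: int) -> float:
    token = token.strip()
    if token in MISSING_TOKENS:
        return np.nan
    try:
        return float(token)
    except ValueError as exc:
        raise ParseError(
            f"{path}: line {line_no}: cannot parse value {token!r}"
        ) from exc


def read_matrix(path, dialect: str = "plain") -> ExpressionMatrix:
    """Read a tab-delimited expression matrix.

    Parameters
    ----------
    path : path-like
        File with a condition-name header row and gene identifiers in the
        first column.
    dialect : {"plain", "pcl"}
        ``pcl`` additionally drops a GWEIGHT column and an EWEIGHT row if
        present.

    Raises
    ------
    ParseError
        Ragged rows (naming the offending line) or unparseable values.
    ValidationError
        Duplicate gene identifiers or an all-missing matrix.
    """
    if dialect not in ("plain", "pcl"):
        raise ValidationError(f"unknown dialect {dialect!r}")
    path = Path(path)
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh, delimiter="\t"))
    rows = [r for r in rows if r]  # drop blank lines
    if len(rows) < 2:
        raise ParseError(f"{path}: needs a header row and at least one gene row")

    header = [c.strip() for c in rows[0]]
    n_fields = len(header)
    drop_cols: set[int] = set()
    if dialect == "pcl":
        drop_cols = {j for j, name in enumerate(header[1:], start=1)
                     if name.upper() == "GWEIGHT"}
    condition_ids = [header[j] for j in range(1, n_fields) if j not in drop_cols]

    gene_ids: list[str] = []
    data: list[list[float]] = []
    for line_no, row in enumerate(rows[1:], start=2):
        if len(row) != n_fields:
            raise ParseError(
                f"{path}: line {line_no}: expected {n_fields} fields, got {len(row)}"
            )
        gid = row[0].strip()
        if dialect == "pcl" and gid.upper() == "EWEIGHT":
            continue
        gene_ids.append(gid)
        data.append(
            [_parse_value(row[j], path, line_no)
             for j in range(1, n_fields) if j not in drop_cols]
        )

    if len(set(gene_ids)) != len(gene_ids):
        seen: set[str] = set()
        dup = next(g for g in gene_ids if g in seen or seen.add(g))  # type: ignore[func-returns-value]
        raise ValidationError(f"{path}: duplicate gene identifier {dup!r}")
    return ExpressionMatrix(gene_ids, condition_ids, np.asarray(data, dtype=float))


def write_matrix(m: ExpressionMatrix, path, dialect: str = "plain") -> None:
    """Write ``m`` tab-delimited; missing cells become ``NA``.

    Values are written with 17 significant digits so a read/write round
    trip is lossless to at least 12 significant digits.
    """
    if dialect not in ("plain", "pcl"):
        raise ValidationError(f"unknown dialect {dialect!r}")
    path = Path(path)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        if dialect == "pcl":
            w.writerow(["YORF", "GWEIGHT"] + m.condition_ids)
            w.writerow(["EWEIGHT", ""] + ["1"] * m.n_conditions)
        else:
            w.writerow(["GID"] + m.condition_ids)
        for i, gid in enumerate(m.gene_ids):
            vals = ["NA" if np.isnan(v) else format(v, ".17g") for v in m.values[i]]
            if dialect == "pcl":
                w.writerow([gid, "1"] + vals)
            else:
                w.writerow([gid] + vals)


def build_reference_matrix(
    m: ExpressionMatrix, max_mv_per_condition: int | None = None
) -> ExpressionMatrix:
    """Construct a complete (MV-free) reference matrix.

    Conditions whose missing count exceeds ``max_mv_per_condition`` are
    dropped first (skipped when None), then every gene with at least one
    remaining missing value is removed. Ordering is preserved and no
    retained value is altered.
    """
    out = m
    if max_mv_per_condition is not None:
        if max_mv_per_condition < 0:
            raise ValidationError("max_mv_per_condition must be >= 0")
        mv_per_cond = np.isnan(out.values).sum(axis=0)
        keep = np.flatnonzero(mv_per_cond <= max_mv_per_condition)
        if len(keep) < 2:
            raise ValidationError("fewer than 2 conditions survive the filter")
        out = out.take_conditions(keep)
    keep_genes = np.flatnonzero(~np.isnan(out.values).any(axis=1))
    if len(keep_genes) < 2:
        raise ValidationError("fewer than 2 genes survive the filter")
    return out.take_genes(keep_genes)


def subsample_genes(
    m: ExpressionMatrix, fraction: float, seed: int
) -> ExpressionMatrix:
    """Uniformly subsample ``round(fraction * G)`` genes without replacement.

    Deterministic given ``seed``; the retained genes keep their original
    relative order.
    """
    if not 0 < fraction <= 1:
        raise ValidationError("fraction must be in (0, 1]")
    g = m.n_genes
    count = int(round(fraction * g))
    if count < 2:
        raise ValidationError("subsample would retain fewer than 2 genes")
    if count == g:
        return m.copy()
    rng = np.random.default_rng(seed)
    chosen = np.sort(rng.choice(g, size=count, replace=False))
    return m.take_genes(chosen)
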