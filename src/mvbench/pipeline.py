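"""Orchestrate the full benchmark sweep and aggregate its records.

The design follows the simulate-mask -> impute -> score -> cluster ->
score pipeline: for every dataset a complete reference matrix and its
reference clusterings (RC) are fixed; for each (scope, tau, replicate)
cell one mask is simulated and shared by every method (pairwise win
rates require paired simulations); each completed matrix is re-clustered
(GC) and compared to RC.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import ExpressionMatrix, ValidationError
from .impute import MethodSpec, impute
from .io import build_reference_matrix
from .masking import simulate_extreme_mask, simulate_mask, spawn_rng
from .metrics import pairwise_win_matrix, predicted_true_correlation, rmse
from .stability import (
    LINKAGES,
    Partition,
    car,
    cpp,
    cpp_f,
    distance_matrix,
    hierarchical_cluster,
    kmeans_cluster,
)
from .synthetic import SyntheticSpec, generate_dataset

__all__ = ["BenchmarkConfig", "run_benchmark", "summarize", "default_tau_grid"]

logger = logging.getLogger(__name__)


def default_tau_grid() -> list[float]:
    """The canonical sweep: 0.5% to 50% missing values by steps of 0.5%."""
    return [round(0.5 * i, 1) for i in range(1, 101)]


@dataclass
class BenchmarkConfig:
    """The experimental design of one benchmark sweep."""

    datasets: dict[str, ExpressionMatrix | SyntheticSpec]
    methods: list[MethodSpec]
    tau_grid: list[float] = field(default_factory=default_tau_grid)
    replicates: int = 100
    scopes: tuple[str, ...] = ("all",)
    extreme_fraction: float = 0.01
    clustering: list[tuple[str, int]] = field(default_factory=list)
    master_seed: int = 0
    output_dir: str | Path | None = None

    def __post_init__(self) -> None:
        if not self.datasets:
            raise ValidationError("at least one dataset is required")
        if not self.methods:
            raise ValidationError("at least one method is required")
        if self.replicates < 1:
            raise ValidationError("replicates must be >= 1")
        for tau in self.tau_grid:
            if not 0 < tau <= 50:
                raise ValidationError("tau values must be in (0, 50]")
        for scope in self.scopes:
            if scope not in ("all", "extreme"):
                raise ValidationError(f"unknown scope {scope!r}")
        for alg, k in self.clustering:
            if alg != "kmeans" and alg not in LINKAGES:
                raise ValidationError(f"unknown clustering algorithm {alg!r}")
            if k < 1:
                raise ValidationError("cluster count must be >= 1")

    @property
    def n_simulations_per_method(self) -> int:
        """Design cells per method and scope: datasets x tau levels x replicates."""
        return len(self.datasets) * len(self.tau_grid) * self.replicates

    @property
    def n_records(self) -> int:
        return (
            self.n_simulations_per_method * len(self.methods) * len(self.scopes)
        )


def _resolve_dataset(src) -> ExpressionMatrix:
    if isinstance(src, SyntheticSpec):
        return generate_dataset(src)[0]
    if isinstance(src, ExpressionMatrix):
        return src if src.is_complete else build_reference_matrix(src)
    raise ValidationError(f"cannot interpret dataset source {type(src).__name__}")


def _cluster(
    m: ExpressionMatrix, alg: str, k: int, seed: int, source: str
) -> Partition:
    if alg == "kmeans":
        return kmeans_cluster(m, k, seed=seed, source=source)
    return hierarchical_cluster(distance_matrix(m), alg, k, source=source)


def run_benchmark(config: BenchmarkConfig, resume: bool = False) -> pd.DataFrame:
    """Run the sweep; returns one record per (dataset, method, scope, tau,
    replicate), written incrementally when ``output_dir`` is set.

    Fully deterministic given ``master_seed``: each design cell draws its
    mask from an independently derived substream, and every method of a
    cell imputes the identical mask. Per-cell failures are recorded and
    skipped, never fatal.
    """
    out_path = None
    done: set[tuple] = set()
    if config.output_dir is not None:
        out_dir = Path(config.output_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        out_path = out_dir / "records.tsv"
        if resume and out_path.exists():
            prev = pd.read_csv(out_path, sep="\t")
            done = {
                (r.dataset, r.method, r.scope, float(r.tau), int(r.replicate))
                for r in prev.itertuples()
            }
        elif out_path.exists():
            out_path.unlink()

    rows: list[dict] = []
    failures: list[str] = []
    for d_idx, (name, src) in enumerate(config.datasets.items()):
        ref = _resolve_dataset(src)
        rc: dict[tuple[str, int], Partition] = {}
        for c_idx, (alg, k) in enumerate(config.clustering):
            seed = int(spawn_rng(config.master_seed, d_idx, 9000 + c_idx)
                       .integers(2**31))
            rc[(alg, k)] = _cluster(ref, alg, k, seed, "RC")

        for s_idx, scope in enumerate(config.scopes):
            for t_idx, tau in enumerate(config.tau_grid):
                for rep in range(config.replicates):
                    cell_rng = spawn_rng(
                        config.master_seed, d_idx, s_idx, t_idx, rep
                    )
                    cell_seed = int(cell_rng.integers(2**31))
                    if scope == "all":
                        data = simulate_mask(ref, tau, cell_seed)
                    else:
                        data = simulate_extreme_mask(
                            ref, tau, config.extreme_fraction, cell_seed
                        )
                    for spec in config.methods:
                        key = (name, spec.name, scope, float(tau), rep)
                        if key in done:
                            continue
                        try:
                            row = _run_cell(
                                config, name, ref, rc, scope, tau, rep,
                                data, spec, cell_seed,
                            )
                        except Exception as exc:  # per-cell isolation
                            failures.append(f"{key}: {exc}")
                            logger.warning("cell %s failed: %s", key, exc)
                            continue
                        rows.append(row)
                        if out_path is not None:
                            pd.DataFrame([row]).to_csv(
                                out_path, sep="\t", mode="a", index=False,
                                header=not out_path.exists(),
                            )
    if failures:
        logger.warning("%d cells failed: %s", len(failures), failures[:10])
    result = pd.DataFrame(rows)
    result.attrs["failures"] = failures
    return result


def _run_cell(config, name, ref, rc, scope, tau, rep, data, spec, cell_seed):
    result = impute(spec, data)
    row = {
        "dataset": name,
        "method": spec.name,
        "scope": scope,
        "tau": float(tau),
        "replicate": rep,
        "n_entries": data.n_masked,
        "rmse": rmse(result, data) if data.n_masked else np.nan,
        "r": np.nan,
        "n_fallback": result.params.get("n_fallback", 0),
    }
    if data.n_masked >= 3:
        r = predicted_true_correlation(result, data)
        row["r"] = np.nan if r is None else r
    for c_idx, (alg, k) in enumerate(config.clustering):
        gc = _cluster(result.completed, alg, k, cell_seed + c_idx + 1, "GC")
        reference = rc[(alg, k)]
        tag = f"{alg}{k}"
        row[f"cpp_{tag}"] = cpp(reference, gc)
        row[f"cpp_f_{tag}"] = cpp_f(reference, gc, result.completed)
        row[f"car_{tag}"] = car(reference, gc)
    return row


def summarize(records: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Aggregate a record table into the three canonical summaries.

    Returns ``mean_rmse`` (methods x datasets grid with row/column
    means), ``wins`` (pooled pairwise win matrix), and ``stability``
    (mean CPP/CPP_f/CAR per method and clustering algorithm) when
    clustering columns are present.
    """
    if records is None or len(records) == 0:
        raise ValidationError("no records to summarize")
    out: dict[str, pd.DataFrame] = {}

    grid = records.pivot_table(
        index="method", columns="dataset", values="rmse", aggfunc="mean"
    )
    grid["mean"] = grid.mean(axis=1)
    grid.loc["mean"] = grid.mean(axis=0)
    out["mean_rmse"] = grid

    if records["method"].nunique() >= 2:
        out["wins"] = pairwise_win_matrix(records)

    stab_cols = [c for c in records.columns
                 if c.startswith(("cpp_", "car_")) and not c.startswith("cpp_f_")]
    stab_cols += [c for c in records.columns if c.startswith("cpp_f_")]
    if stab_cols:
        out["stability"] = records.groupby("method")[sorted(stab_cols)].mean()
    return out
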