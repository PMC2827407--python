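"""Synthetic expression matrices with known co-expression clusters.

The generator emulates the structure of small refined microarray
compendia: G genes x n conditions (n around 6-16) of log2 ratios,
C co-expression clusters, optional kinetic (smooth temporal) centroid
profiles, and a fraction of near-flat "null" genes that real analyses
retain when no profile filtering is applied. It produces complete
matrices so every pipeline stage (masking, imputation, clustering) can
be tested without external downloads, with the generating labels
returned as the ground-truth partition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import ExpressionMatrix, ValidationError
from .stability import Partition

__all__ = ["SyntheticSpec", "generate_dataset"]


@dataclass
class SyntheticSpec:
    """Parameters of a synthetic clustered expression dataset.

    Defaults are shaped on a refined yeast subset of ~800 genes x 8
    conditions: G=500 genes, n=8 conditions, C=10 clusters, centroid
    spread 1.0 and within-cluster noise 0.25 (log2 units), with 10%
    flat genes.
    """

    G: int = 500
    n: int = 8
    C: int = 10
    kinetic: bool = False
    sigma_between: float = 1.0
    sigma_within: float = 0.25
    flat_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.G >= self.C >= 1):
            raise ValidationError("need G >= C >= 1")
        if self.n < 2:
            raise ValidationError("need n >= 2 conditions")
        if self.sigma_between < 0 or self.sigma_within < 0:
            raise ValidationError("spreads must be >= 0")
        if not 0 <= self.flat_fraction < 1:
            raise ValidationError("flat_fraction must be in [0, 1)")


def generate_dataset(spec: SyntheticSpec) -> tuple[ExpressionMatrix, Partition]:
    """Generate a complete matrix plus its ground-truth partition.

    Non-kinetic centroids are drawn independently per condition from
    N(0, sigma_between^2); kinetic centroids are smooth sinusoids
    a*sin(2*pi*t/n + phi) + b with cluster-specific (a, phi, b) drawn
    from seeded uniforms. Each non-flat gene is its cluster centroid
    plus N(0, sigma_within^2) noise; flat genes are pure noise around 0
    and carry a dedicated extra label. Deterministic given the seed.
    """
    rng = np.random.default_rng(spec.seed)
    g, n, c = spec.G, spec.n, spec.C
    n_flat = int(round(spec.flat_fraction * g))
    n_clustered = g - n_flat
    if n_clustered < c:
        raise ValidationError("too few non-flat genes to populate every cluster")

    if spec.kinetic:
        t = np.arange(n) / n
        amp = rng.uniform(0.5 * spec.sigma_between, 2.0 * spec.sigma_between, c)
        phase = rng.uniform(0.0, 2.0 * np.pi, c)
        offset = rng.uniform(-spec.sigma_between, spec.sigma_between, c)
        centroids = (
            amp[:, None] * np.sin(2.0 * np.pi * t[None, :] + phase[:, None])
            + offset[:, None]
        )
    else:
        centroids = rng.normal(0.0, spec.sigma_between, size=(c, n))

    # every cluster gets at least one gene; the rest are assigned uniformly
    labels = np.concatenate(
        [np.arange(c), rng.integers(0, c, size=n_clustered - c)]
    )
    values = centroids[labels] + rng.normal(0.0, spec.sigma_within, (n_clustered, n))
    if n_flat:
        flat = rng.normal(0.0, spec.sigma_within, (n_flat, n))
        values = np.vstack([values, flat])
        labels = np.concatenate([labels, np.full(n_flat, c)])

    perm = rng.permutation(g)
    values, labels = values[perm], labels[perm]

    matrix = ExpressionMatrix(
        [f"G{i + 1:05d}" for i in range(g)],
        [f"cond{j + 1}" for j in range(n)],
        values,
    )
    partition = Partition(
        labels, K=c + (1 if n_flat else 0), source="RC", algorithm="generator"
    )
    return matrix, partition
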