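import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mvbench import ExpressionMatrix, MaskedDataset

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_matrix(values, gene_prefix="g", cond_prefix="c") -> ExpressionMatrix:
    values = np.asarray(values, dtype=float)
    g, n = values.shape
    return ExpressionMatrix(
        [f"{gene_prefix}{i}" for i in range(g)],
        [f"{cond_prefix}{j}" for j in range(n)],
        values,
    )


def mask_entries(m: ExpressionMatrix, positions) -> MaskedDataset:
    """Mask explicit positions of a complete matrix."""
    positions = np.asarray(positions, dtype=int).reshape(-1, 2)
    truth = m.values[positions[:, 0], positions[:, 1]]
    return MaskedDataset(m, positions, truth, tau=0.0)


@pytest.fixture
def random_complete():
    """A 12 x 6 complete matrix of seeded standard-normal log ratios."""
    rng = np.random.default_rng(42)
    return make_matrix(rng.normal(0, 1, (12, 6)))


@pytest.fixture
def random_masked(random_complete):
    """The same matrix with 8 seeded masked entries."""
    rng = np.random.default_rng(7)
    flat = rng.choice(random_complete.values.size, size=8, replace=False)
    pos = np.column_stack(np.divmod(np.sort(flat), random_complete.n_conditions))
    return mask_entries(random_complete, pos)
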