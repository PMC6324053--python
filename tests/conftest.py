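import numpy as np
import pytest

from coexbuild import ModuleSpec, build_platform, center_genes, generate_expression
from coexbuild.types import ExpressionMatrix

# Desk-scale ensemble profile used by the heavier statistical tests:
# 50 repetitions at subsample fraction 0.5 keeps the expected number of
# signal-bearing repetitions for a rank-1 module at 25 (the production
# profile, 1000 repetitions at fraction 0.1, expects 100).
DESK_REPS = 50
DESK_FRACTION = 0.5


@pytest.fixture
def rng():
    return np.random.default_rng(20260101)


@pytest.fixture
def small_counts():
    """4 genes x 3 samples count matrix with known column sums and row means."""
    values = np.array(
        [
            [1_000_000.0, 800_000.0, 900_000.0],
            [1_400_000.0, 1_199_999.0, 1_000_000.0],
            [100_000.0, 0.0, 100_000.0],
            [0.0, 0.0, 0.0],
        ]
    )
    return ExpressionMatrix(
        gene_ids=("gA", "gB", "gC", "gD"),
        sample_ids=("s1", "s2", "s3"),
        values=values,
        scale="counts",
    )


@pytest.fixture(scope="session")
def two_module_spec():
    """Two planted 10-gene modules (within-module Pearson ~0.8) in a
    200-gene, 200-sample background."""
    return ModuleSpec(
        n_modules=2,
        genes_per_module=10,
        within_corr=0.8,
        background_genes=180,
        n_samples=200,
        seed=11,
    )


@pytest.fixture(scope="session")
def two_module_platform(two_module_spec):
    m = center_genes(generate_expression(two_module_spec))
    return build_platform(
        m,
        n_repetitions=DESK_REPS,
        subsample_fraction=DESK_FRACTION,
        seed=111,
    )


def module_masks(spec):
    """(within, between) boolean masks over off-diagonal gene pairs."""
    n = spec.total_genes
    within = np.zeros((n, n), dtype=bool)
    for m in range(spec.n_modules):
        lo = m * spec.genes_per_module
        hi = lo + spec.genes_per_module
        within[lo:hi, lo:hi] = True
    np.fill_diagonal(within, False)
    off = ~np.eye(n, dtype=bool)
    return within, off & ~within
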