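import numpy as np
import pytest

from dendrosplit import (
    DendroSplitConfig,
    ExpressionMatrix,
    GeneFilterParams,
    SyntheticSpec,
    points_to_expression,
    run_dendrosplit,
    simulate_scrna,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20260101)


@pytest.fixture
def small_matrix():
    """3 cells x 4 genes of raw counts, with one all-zero gene."""
    return ExpressionMatrix(
        values=np.array(
            [
                [0.0, 5.0, 0.0, 2.0],
                [1.0, 0.0, 0.0, 9.0],
                [3.0, 2.0, 0.0, 0.0],
            ]
        ),
        cell_ids=["c1", "c2", "c3"],
        gene_ids=["g1", "g2", "g3", "g4"],
    )


def random_expression(rng, n_cells=8, n_genes=6, log_transformed=False):
    values = rng.random((n_cells, n_genes)) * 10
    return ExpressionMatrix(
        values=values,
        cell_ids=[f"c{i}" for i in range(n_cells)],
        gene_ids=[f"g{j}" for j in range(n_genes)],
        log_transformed=log_transformed,
    )


def well_separated_spec(seed, n_types=3):
    """A planted-type expression fixture with strong, clean markers."""
    return SyntheticSpec(
        n_types=n_types,
        cells_per_type=(40,) * n_types,
        n_genes=120,
        markers_per_type=8,
        marker_log_fold=1.5,
        dropout_rate=0.0,
        seed=seed,
    )
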