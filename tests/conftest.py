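import numpy as np
import pandas as pd
import pytest

from orthostage import ExpressionSimConfig, GenomeSimConfig, generate_genomes, simulate_counts


@pytest.fixture(scope="session")
def tiny_genomes():
    """Small planted-truth genome pair: 12 genes, 3 decoys, 2 intron shifts."""
    config = GenomeSimConfig(
        n_genes=12, n_decoy_duplicates=3, n_intron_shift_genes=2, seed=7
    )
    return generate_genomes(config)


@pytest.fixture(scope="session")
def small_counts():
    """Two-species stage-structured counts at reduced scale (fast tests)."""
    config = ExpressionSimConfig(cells_per_stage=12, n_genes=400, seed=11)
    matrices, truth = simulate_counts(config)
    return config, matrices, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def make_counts(counts, phenotype=None, species="A", individual=None):
    """Build a CountMatrix from a raw array with minimal metadata."""
    from orthostage import CountMatrix

    counts = np.asarray(counts)
    cells = [f"c{i}" for i in range(counts.shape[0])]
    genes = [f"g{j}" for j in range(counts.shape[1])]
    meta = pd.DataFrame(
        {
            "species": species,
            "phenotype": phenotype if phenotype is not None else ["p0"] * len(cells),
            "individual": individual if individual is not None else ["i0"] * len(cells),
        },
        index=cells,
    )
    return CountMatrix(counts, cells, genes, meta)
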