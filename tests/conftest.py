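import numpy as np
import pytest

from coexnet.synthetic_data import (ExpressionStudy, GeneSetCollection,
                                    ModuleSpec, SyntheticConfig,
                                    generate_expression_study)


@pytest.fixture(scope="session")
def small_study() -> ExpressionStudy:
    """600 cells x 300 genes, one always-active planted module of 30 genes."""
    config = SyntheticConfig(
        n_cells=600, n_genes=300, n_timepoints=3,
        modules=(ModuleSpec(tuple(range(30)), (0, 1, 2), 0.9),),
        dropout_rate=0.1, seed=11)
    return generate_expression_study(config)


@pytest.fixture(scope="session")
def toy_gene_sets() -> GeneSetCollection:
    return GeneSetCollection("toy", {
        "SET_A": ("first", frozenset({"G1", "G2", "G3"})),
        "SET_B": ("second", frozenset({"G4", "G5", "G6", "G7"})),
    })


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
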