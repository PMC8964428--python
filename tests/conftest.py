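import numpy as np
import pytest

from cdp.datatypes import CASE, CONTROL, ExpressionMatrix, GeneSetCollection
from cdp.simulate import SimulationConfig, simulate_gene_sets, simulate_paired_cohort


@pytest.fixture
def small_expr() -> ExpressionMatrix:
    """3 genes x 4 samples (2 case, 2 control), fixed values."""
    values = np.array(
        [
            [4.0, 4.0, 2.0, 2.0],
            [1.0, 3.0, 2.0, 2.0],
            [5.0, 7.0, 6.0, 8.0],
        ]
    )
    return ExpressionMatrix(
        ["gA", "gB", "gC"],
        ["s1", "s2", "s3", "s4"],
        values,
        [CASE, CASE, CONTROL, CONTROL],
    )


@pytest.fixture
def planted_cohort():
    """Synthetic paired cohort with one up- and one down-shifted gene set."""
    cfg = SimulationConfig(
        n_genes=400,
        n_sets=8,
        set_size_range=(15, 30),
        n_case=12,
        n_control=12,
        planted_up={"SET_000": 2.0},
        planted_down={"SET_001": 2.0},
        seed=123,
    )
    sets = simulate_gene_sets(cfg)
    expr = simulate_paired_cohort(cfg, sets)
    return cfg, sets, expr


@pytest.fixture
def toy_sets() -> GeneSetCollection:
    return GeneSetCollection(
        {"PATH_A": ["g1", "g2", "g3"], "PATH_B": ["g4", "g5"]},
        {"PATH_A": "first", "PATH_B": "second"},
    )
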