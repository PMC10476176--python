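import numpy as np
import pandas as pd
import pytest

from phyloexpr.io import ExpressionMatrix, LifeHistoryTable, SampleTable
from phyloexpr.trees import Phylogeny


@pytest.fixture
def small_tree() -> Phylogeny:
    """((A:1,B:1):1,C:2); — covariance and distances known by hand."""
    return Phylogeny.from_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def four_tip_tree() -> Phylogeny:
    return Phylogeny.from_newick("(((A:1,B:1):1,C:2):1,D:3);")


@pytest.fixture
def star_tree_16() -> Phylogeny:
    tips = ",".join(f"t{i}:1" for i in range(16))
    return Phylogeny.from_newick(f"({tips});")


@pytest.fixture
def sim_tree_32():
    from phyloexpr.simulate import simulate_tree

    return simulate_tree(32, seed=101)


@pytest.fixture
def sim_tree_64():
    from phyloexpr.simulate import simulate_tree

    return simulate_tree(64, seed=202)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def counts_matrix(rng) -> ExpressionMatrix:
    genes = [f"g{i}" for i in range(50)]
    samples = [f"s{i}" for i in range(6)]
    vals = pd.DataFrame(
        rng.poisson(40, size=(50, 6)).astype(float), index=genes, columns=samples
    )
    meta = pd.DataFrame(
        {
            "species": [f"sp{i // 2}" for i in range(6)],
            "tissue": "liver",
            "replicate": [i % 2 + 1 for i in range(6)],
            "batch": "b1",
        },
        index=pd.Index(samples, name="sample_id"),
    )
    return ExpressionMatrix(vals, samples=SampleTable(meta))


@pytest.fixture
def life_history_table() -> LifeHistoryTable:
    frame = pd.DataFrame(
        {
            "AW": [20.0, 400.0, 5000.0, 70000.0],
            "ML": [3.0, 12.0, 25.0, 60.0],
            "FTM": [0.2, 0.8, 2.0, 8.0],
        },
        index=pd.Index(["A", "B", "C", "D"], name="species"),
    )
    return LifeHistoryTable(frame)
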