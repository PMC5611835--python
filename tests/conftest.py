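import numpy as np
import pytest

from grnloop.io import CONTROL, DISEASED, ExpressionMatrix, GeneSetCatalog, SeedList


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_matrix():
    """5 genes x 6 samples (4 diseased, 2 control), fixed values."""
    gen = np.random.default_rng(7)
    values = gen.normal(8.0, 1.0, size=(5, 6))
    return ExpressionMatrix(
        gene_ids=[f"G{i}" for i in range(5)],
        sample_ids=[f"s{i}" for i in range(6)],
        values=values,
        phenotype=[DISEASED] * 4 + [CONTROL] * 2,
    )


@pytest.fixture
def tiny_catalog():
    return GeneSetCatalog(
        {
            "P1": ("pathway one", frozenset({"A", "B", "C"})),
            "P2": ("pathway two", frozenset({"C", "D"})),
        }
    )


@pytest.fixture
def abc_seed():
    return SeedList(["A", "B", "C"])
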