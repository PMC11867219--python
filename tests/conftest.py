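import numpy as np
import pandas as pd
import pytest

from fhburden.burden import ExonStructure, GenotypeMatrix
from fhburden.models import CohortCells


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_matrix(rng) -> GenotypeMatrix:
    """20 samples x 10 variants across two genes, with some missing calls."""
    n, m = 20, 10
    calls = rng.choice([0.0, 0.0, 0.0, 1.0, 2.0], size=(n, m))
    calls[rng.random((n, m)) < 0.05] = np.nan
    variants = pd.DataFrame({
        "gene": ["GENE1"] * 6 + ["GENE2"] * 4,
        "chrom": "1",
        "pos": np.arange(100, 100 + m * 10, 10),
        "af": rng.uniform(0, 0.01, m),
    }, index=[f"v{i}" for i in range(m)])
    return GenotypeMatrix(samples=[f"s{i}" for i in range(n)],
                          variants=variants, calls=calls)


@pytest.fixture
def three_exon_plus() -> ExonStructure:
    return ExonStructure(gene="G", strand="+",
                         exons=((1, 100), (101, 200), (301, 400)))


def random_cells(rng, scale: float = 2000.0) -> CohortCells:
    """A random strictly-positive 16-cell table (every stratum populated)."""
    counts = rng.integers(5, int(scale), size=(2, 2, 2, 2)).astype(float)
    return CohortCells(counts)
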