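import numpy as np
import pytest

from normeval.core_data import CountMatrix, GeneAnnotation
from normeval.synthetic import scrna_config, simulate_counts

#: seed for the shared 2000x20 single-cell-like fixture
FIXTURE_SEED = 7


def make_matrix(values, gene_prefix="g", sample_prefix="s"):
    values = np.asarray(values, dtype=float)
    m, n = values.shape
    return CountMatrix(
        values,
        tuple(f"{gene_prefix}{i + 1}" for i in range(m)),
        tuple(f"{sample_prefix}{j + 1}" for j in range(n)),
    )


def random_positive_matrix(rng, m, n, scale=100.0):
    """Strictly positive random matrix (no zeros, no ties)."""
    return make_matrix(rng.lognormal(np.log(scale), 1.0, size=(m, n)))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_matrix():
    return make_matrix([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]])


@pytest.fixture
def annotated_matrix():
    """5 nuclear + 1 mitochondrial + 2 spike-in genes, integer counts."""
    values = np.array(
        [
            [100, 200],
            [300, 100],
            [200, 250],
            [250, 150],
            [50, 100],     # nuclear, total 900 / 800
            [50, 60],      # mitochondrial
            [70, 90],      # spike-in
            [30, 10],      # spike-in
        ],
        dtype=float,
    )
    gene_ids = ("n1", "n2", "n3", "n4", "n5", "mt1", "ercc1", "ercc2")
    matrix = CountMatrix(values, gene_ids, ("s1", "s2"))
    annotation = GeneAnnotation(
        gene_class={
            "mt1": "mitochondrial",
            "ercc1": "spike_in",
            "ercc2": "spike_in",
        }
    )
    return matrix, annotation


@pytest.fixture(scope="session")
def scrna_fixture():
    """2000x20 single-cell-like matrix with known depths (shared, seeded)."""
    config = scrna_config(
        n_genes=2000,
        n_samples=20,
        de_fraction=0.1,
        depth_log_range=(np.log(0.25), np.log(4.0)),
        seed=FIXTURE_SEED,
    )
    return simulate_counts(config)
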