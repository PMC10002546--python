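import numpy as np
import pytest
import scipy.sparse as sp

from crossortho.io_tenx import CountMatrix
from crossortho.study import run_reference_study


def make_counts(dense, species="test", gene_ids=None, symbols=None, barcodes=None):
    """CountMatrix from a dense array, with autogenerated metadata."""
    dense = np.asarray(dense)
    n_genes, n_cells = dense.shape
    gene_ids = gene_ids or [f"G{i}" for i in range(n_genes)]
    symbols = symbols or [f"S{i}" for i in range(n_genes)]
    barcodes = barcodes or [f"BC{i}" for i in range(n_cells)]
    return CountMatrix(
        species=species,
        counts=sp.csr_matrix(dense),
        gene_ids=gene_ids,
        gene_symbols=symbols,
        cell_barcodes=barcodes,
    )


@pytest.fixture(scope="session")
def study_runs():
    """Full-pipeline runs under the reference study conditions, seeds 1-5.

    Shared across the end-to-end anchoring and conserved-marker tests;
    this is the most expensive fixture in the suite.
    """
    return {seed: run_reference_study(seed) for seed in range(1, 6)}


@pytest.fixture()
def rng():
    return np.random.default_rng(20230301)
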