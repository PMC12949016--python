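import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from xci_scope.core_io import AnnotatedCountMatrix, attach_normalized
from xci_scope.synthetic_data import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Reduced cohort (two XX samples + one XY) shared across module tests."""
    cfg = SimulationConfig(cells_per_sample=(400, 400, 300), seed=7)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def small_matrix(small_cohort):
    return attach_normalized(small_cohort.matrix)


def make_matrix(counts, chroms=None, statuses=None, symbols=None, sexes=None, samples=None):
    """Hand-crafted AnnotatedCountMatrix for closed-form unit tests."""
    counts = np.asarray(counts)
    n_cells, n_genes = counts.shape
    chroms = chroms or ["1"] * n_genes
    if statuses is None:
        statuses = ["not_X" if c != "X" else "unclassified" for c in chroms]
    gene_ids = [f"g{j}" for j in range(n_genes)]
    genes = pd.DataFrame(
        {
            "symbol": symbols or gene_ids,
            "chromosome": chroms,
            "start": np.arange(1, n_genes + 1) * 1000,
            "end": np.arange(1, n_genes + 1) * 1000 + 100,
            "xci_status": statuses,
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )
    cell_meta = pd.DataFrame(
        {
            "sample_id": samples or ["s1"] * n_cells,
            "sex": sexes or ["XX"] * n_cells,
            "cell_type": ["t"] * n_cells,
            "broad_lineage": ["stroma"] * n_cells,
        },
        index=pd.Index([f"c{i}" for i in range(n_cells)], name="barcode"),
    )
    return AnnotatedCountMatrix(counts=sp.csr_matrix(counts), cell_meta=cell_meta, genes=genes)
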