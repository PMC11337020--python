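import numpy as np
import pytest
import scipy.sparse as sp

from mfclone.io import CountMatrix
from mfclone.synthetic import CNVBlockSpec, CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Two-patient cohort exercising QC, clonotyping, CNV and velocity."""
    cfg = CohortConfig(
        seed=101,
        n_patients=2,
        n_cells=(220, 220),
        malignant_fraction=(0.5, 0.9),
        n_subpops=(2, 1),
        cnv_blocks={
            0: [CNVBlockSpec("1", 5, 30, 1.5)],
            1: [CNVBlockSpec("7", 5, 30, 0.5)],
        },
        dynamics_regime=("steady", "induction"),
        nonproductive_patients=(1,),
    )
    return generate_cohort(cfg)


def random_count_matrix(rng, n_genes=50, n_cells=30, sample_id="S", density=0.4):
    counts = (rng.random((n_genes, n_cells)) < density) * rng.integers(
        1, 20, (n_genes, n_cells)
    )
    return CountMatrix(
        gene_ids=[f"ID{i}" for i in range(n_genes)],
        gene_symbols=[f"G{i}" for i in range(n_genes)],
        cell_barcodes=[f"BC{i:04d}-1" for i in range(n_cells)],
        counts=sp.csr_matrix(counts.astype(float)),
        sample_id=sample_id,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)
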