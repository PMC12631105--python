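import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from metaniche import CohortConfig, CountMatrix, PlantedProgram, generate_cohort


def make_matrix(counts, gene_ids=None, cell_ids=None, samples=None, groups=None,
                tissues=None, celltypes=None):
    """CountMatrix from a dense genes x cells array with defaultable metadata."""
    counts = np.asarray(counts)
    G, N = counts.shape
    gene_ids = gene_ids or [f"g{i}" for i in range(G)]
    cell_ids = cell_ids or [f"c{i}" for i in range(N)]
    meta = pd.DataFrame(
        {
            "sample": samples or ["S1"] * N,
            "group": groups or ["NMI"] * N,
            "tissue": tissues or ["UCB"] * N,
            "celltype": celltypes or ["CT1"] * N,
        },
        index=pd.Index(cell_ids, name="cell_id"),
    )
    return CountMatrix(sp.csr_matrix(counts), gene_ids, cell_ids, meta)


@pytest.fixture(scope="session")
def small_cohort():
    """3-sample cohort with one planted program and MI-basal MHC-II positives."""
    cfg = CohortConfig(
        n_samples=3,
        cells_per_sample=120,
        n_genes=300,
        planted_programs=[PlantedProgram(tuple(range(40, 90)), 0.3, 2.0)],
        group_labels={"S01": "MI-basal", "S02": "MI-luminal", "S03": "NMI"},
        mhc2_positive_fraction_by_group={"MI-basal": 0.2},
        seed=42,
    )
    matrix, truth = generate_cohort(cfg)
    return cfg, matrix, truth
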