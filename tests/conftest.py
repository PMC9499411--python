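import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

import segstable as st

#: reduced simulation used for structural/invariant tests — small enough to
#: run many seeds, still exercising 2 stages × 2 tissues × 2 samples × 3 types
SMALL_SIM = dict(
    n_genes=300,
    cells_per_cluster=120,
    clusters_per_cell_type=1,
    cell_types=("T", "B", "NK"),
    samples_per_tissue=2,
    tissues_per_stage=2,
    n_global_seg=20,
    n_tissue_seg=8,
    n_cell_specific=9,
    n_marker=6,
    n_silent=20,
)

#: pipeline parameters scaled to the small simulation
SMALL_PARAMS = dict(n=10, m=100, r=30, K=150, S=80)


def small_config(seed=11, **over):
    return st.SimConfig(seed=seed, **{**SMALL_SIM, **over})


def small_params(seed=11, **over):
    return st.PipelineParams(seed=seed, **{**SMALL_PARAMS, **over})


@pytest.fixture(scope="session")
def small_dataset():
    return st.simulate_dataset(small_config())


@pytest.fixture(scope="session")
def small_result(small_dataset):
    cm, _ = small_dataset
    return st.run_pipeline(cm, small_params())


@pytest.fixture
def toy_cm():
    """4 genes × 6 cells, two clusters of one sample, hand-checkable."""
    counts = np.array(
        [
            [5, 5, 5, 5, 5, 5],    # constant gene
            [1, 2, 3, 4, 5, 6],
            [0, 0, 0, 0, 0, 0],    # silent gene
            [10, 0, 10, 0, 10, 0],
        ]
    )
    meta = pd.DataFrame(
        {
            "sample_id": ["s1"] * 6,
            "tissue": ["lung"] * 6,
            "stage": ["adult"] * 6,
            "cluster_id": ["c1", "c1", "c1", "c2", "c2", "c2"],
            "cell_type": ["T", "T", "T", "B", "B", "B"],
        },
        index=pd.Index([f"cell{i}" for i in range(6)], name="cell_id"),
    )
    return st.CellMatrix(
        counts=sp.csr_matrix(counts),
        gene_ids=np.array([f"g{i}" for i in range(4)], dtype=object),
        cell_ids=meta.index.to_numpy(dtype=object),
        cell_meta=meta,
    )
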