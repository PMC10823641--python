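import math

import numpy as np
import pandas as pd
import pytest

import loykit as lk


def make_table(counts: dict, meta: dict, modality: str = "RNA") -> lk.CellCoverageTable:
    """Small hand-built coverage table; counts maps chrom -> list."""
    counts_df = pd.DataFrame(counts)
    n = len(counts_df)
    counts_df.index = pd.Index([f"c{i}" for i in range(n)], name="cell_id")
    base = {
        "donor_id": ["D0"] * n,
        "sex": ["M"] * n,
        "age": [60.0] * n,
        "cell_type": ["PT"] * n,
        "disease": ["control"] * n,
    }
    base.update(meta)
    return lk.CellCoverageTable(
        modality=modality,
        counts=counts_df,
        meta=pd.DataFrame(base, index=counts_df.index),
    )


@pytest.fixture(scope="session")
def two_celltype_cohort():
    """Cohort with two cell types whose chrY accessibility differs 2x."""
    return lk.CohortConfig(
        n_donors=3,
        n_cells_per_donor=400,
        seed=11,
        celltype_specs=[
            lk.CellTypeSpec("PT", 0.5, 0.0, 1.0),
            lk.CellTypeSpec("TAL", 0.5, 0.0, 0.5),
        ],
        gain_spec=("chr7", 0.0, 1.5),
    )


@pytest.fixture(scope="session")
def small_multiome():
    """A modest multiome cohort with known truth, ambient rate 0."""
    cfg = lk.CohortConfig(
        n_donors=4,
        n_cells_per_donor=500,
        seed=5,
        baseline_loy_logit=math.log(0.15 / 0.85) - 0.02 * 60,
        donor_random_intercept_sd=0.3,
        ambient_y_rate=0.0,
    )
    return lk.simulate_cohort(cfg, make_bin_matrix=False)
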