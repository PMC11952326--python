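import numpy as np
import pandas as pd
import pytest

import degeval as dg


@pytest.fixture
def tiny_dataset():
    """3 samples × 2 genes, one context, control + one perturbation."""
    return dg.PerturbationDataset(
        matrix=np.array([[1.0, 2.0], [3.0, 4.0], [2.0, 6.0]]),
        gene_ids=np.array(["gA", "gB"], dtype=object),
        obs=pd.DataFrame(
            {"context": ["c1", "c1", "c1"], "action": ["0", "0", "stim"]},
            index=["s1", "s2", "s3"],
        ),
        scale="lognorm",
    )


@pytest.fixture(scope="session")
def small_sc():
    """Small PBMC-style simulation shared across tests (read-only)."""
    cfg = dg.pbmc_like_config(n_genes=400, cells_per_pair=60, deg_fraction=0.05)
    return dg.simulate_single_cell(cfg, seed=11)


@pytest.fixture(scope="session")
def small_plate():
    """Small plate-design simulation shared across tests (read-only)."""
    cfg = dg.plate_like_config(n_genes=250, n_perturbations=5, cells_per_pair=12, deg_fraction=0.06)
    return dg.simulate_plate_design(cfg, seed=7)
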