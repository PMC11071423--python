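import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from fmm import io as fio
from fmm import links as lk
from fmm.scenarios import default_study_scenario
from fmm.simulate import simulate_multiome

SCENARIO_SEED = 11


@pytest.fixture(scope="session")
def scenario():
    """One draw of the default study-scale scenario, shared across tests."""
    cfg = default_study_scenario(SCENARIO_SEED)
    ds, truth = simulate_multiome(cfg)
    return cfg, ds, truth


@pytest.fixture(scope="session")
def ilc2_linkdata(scenario):
    """LinkData over the true ILC2 cells of the shared scenario."""
    cfg, ds, truth = scenario
    mask = (truth.labels["cell_type"] == "ILC2").to_numpy()
    ilc2 = ds.subset_cells(mask)
    labels = truth.labels.loc[mask].reset_index(drop=True)
    return lk.LinkData.from_dataset(ilc2), labels


def make_count_matrix(arr, genes=None, cells=None, modality=fio.RNA):
    arr = np.asarray(arr)
    genes = genes or [f"g{i}" for i in range(arr.shape[0])]
    cells = cells or [f"c{i}" for i in range(arr.shape[1])]
    return fio.CountMatrix(sp.csr_matrix(arr), genes, cells, modality)


def make_gene_model(rows):
    return pd.DataFrame(rows, columns=["gene", "chrom", "start", "end", "strand"])
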