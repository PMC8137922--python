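import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from spearatac.containers import SparseCountMatrix
from spearatac.synthetic import SimulationConfig, build_truth, simulate_counts


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A compact screen: 3 targets x 2 sgRNAs + 2 NT sgRNAs, 20 cells each."""
    return SimulationConfig(
        n_targets=3,
        sgrnas_per_target=2,
        n_nt_sgrnas=2,
        cells_per_sgrna=20,
        n_peaks=300,
        n_motifs=6,
        peaks_per_motif=20,
        mean_insertions_per_cell=800.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_screen(small_config):
    """(counts, motifs, gc, truth) for the compact screen."""
    return simulate_counts(small_config, build_truth(small_config))


def truth_assignments(truth) -> pd.DataFrame:
    """Oracle assignment table built from simulation ground truth."""
    return pd.DataFrame(
        {
            "sgrna": truth.cells["sgrna"],
            "target": truth.cells["target"],
            "n_counts": 100,
            "specificity": 1.0,
            "assigned": True,
            "reason": "",
        },
        index=truth.cells.index,
    )


def counts_from_dense(arr, row_prefix="c", col_prefix="p") -> SparseCountMatrix:
    arr = np.asarray(arr)
    return SparseCountMatrix(
        sp.csr_matrix(arr),
        [f"{row_prefix}{i}" for i in range(arr.shape[0])],
        [f"{col_prefix}{j}" for j in range(arr.shape[1])],
    )
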