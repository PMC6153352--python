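import logging

import numpy as np
import pytest
import scipy.sparse as sp

from pvsignal import ReportMatrix, SimulationConfig, simulate

logging.getLogger("pvsignal").setLevel(logging.ERROR)


@pytest.fixture
def tiny_rm():
    """4 reports x 3 drugs x 2 AEs, hand-checkable."""
    X = np.array(
        [
            [1, 0, 1],
            [1, 1, 0],
            [0, 1, 0],
            [0, 0, 1],
        ]
    )
    Y = np.array(
        [
            [1, 0],
            [0, 1],
            [1, 1],
            [0, 0],
        ]
    )
    return ReportMatrix(
        X=sp.csr_matrix(X),
        Y=sp.csr_matrix(Y),
        drug_ids=["A", "B", "C"],
        ae_ids=["e1", "e2"],
    )


@pytest.fixture(scope="session")
def small_db():
    """One modest simulated database shared by read-only tests."""
    cfg = SimulationConfig(
        N=6000, I=20, n_blocks=4, n_true_signals=4, n_confounded_nulls=4, seed=11
    )
    return simulate(cfg)


@pytest.fixture(scope="session")
def medium_db():
    """Larger simulated database for detector behaviour tests."""
    cfg = SimulationConfig(
        N=20000, I=30, n_blocks=10, n_true_signals=10, n_confounded_nulls=10, seed=7
    )
    return simulate(cfg)
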