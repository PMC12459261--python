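import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from scessentials import ExpressionAtlas, SimulationConfig, simulate_atlas


@pytest.fixture
def tiny_atlas() -> ExpressionAtlas:
    """3 genes x 4 cells, two cell types, two platforms, hand-written."""
    counts = np.array([
        [5, 0, 2, 1],
        [0, 0, 0, 3],
        [1, 1, 1, 1],
    ])
    meta = pd.DataFrame({
        "cell_id": ["c1", "c2", "c3", "c4"],
        "cell_type": ["A", "A", "B", "B"],
        "tissue": ["T", "T", "T", "T"],
        "donor": ["d1", "d2", "d1", "d2"],
        "platform": ["p1", "p1", "p2", "p2"],
    })
    return ExpressionAtlas(["g1", "g2", "g3"], sp.csr_matrix(counts), meta)


@pytest.fixture(scope="session")
def small_sim():
    """A modest simulated atlas shared across read-only tests."""
    cfg = SimulationConfig(n_cell_types=3, cells_per_type=100, n_donors=3,
                           n_platforms=2, n_essential_like=15, n_marker_like=6,
                           n_noise=40, seed=123441)
    return simulate_atlas(cfg)
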