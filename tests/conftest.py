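import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from adherenet.connectome import BinaryGraph
from adherenet.io_formats import RunConfig
from adherenet.synthetic_cohort import SimParams, simulate_cohort


def graph_from_edges(n, edges, threshold=0.3, labels=None):
    a = np.zeros((n, n), dtype=np.int8)
    for i, j in edges:
        a[i, j] = a[j, i] = 1
    labels = labels or tuple(f"ROI_{k:03d}" for k in range(n))
    return BinaryGraph(a, labels, threshold)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def small_cohort():
    """A small but fully-featured synthetic cohort (fast to analyse)."""
    params = SimParams(
        n_participants=20, group_sizes=(11, 9), n_roi=25, n_timepoints=60,
        network_sizes=(5, 5, 5, 5, 5), seed=7,
    )
    return simulate_cohort(params)


@pytest.fixture
def fast_config():
    return RunConfig(n_perm=200, louvain_reps=5)
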