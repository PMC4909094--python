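import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from sfconn import CohortSpec, ConnectivityMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_spec():
    """Small, fast cohort used across module tests."""
    return CohortSpec(n_nodes=32, n_controls=4, n_patients=4, ts_length=128, seed=7)


def sym_count_matrix(values):
    """Helper: build a count ConnectivityMatrix from an array-like."""
    v = np.asarray(values, dtype=float)
    return ConnectivityMatrix(v, kind="count")
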