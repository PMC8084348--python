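import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from cttespike import (CoupledPairParams, EmbeddingConfig,
                       build_sample_sets, simulate_coupled_pair,
                       simulate_homogeneous_poisson)


@pytest.fixture(scope="session")
def poisson_pair():
    """Independent unit-rate Poisson pair, 2000 target events."""
    y = simulate_homogeneous_poisson(1.0, 2000, 11, label="Y")
    x = simulate_homogeneous_poisson(1.0, 2000, 13, label="X")
    return y, x


@pytest.fixture(scope="session")
def coupled_pair_small():
    """Coupled pair at the benchmark parameters, 5000 target events."""
    params = CoupledPairParams()
    y, x = simulate_coupled_pair(params, 5000, 7)
    return params, y, x


@pytest.fixture(scope="session")
def tiny_sets():
    """Small sample sets (N <= 200) for exhaustive-oracle comparisons."""
    y = simulate_homogeneous_poisson(1.0, 260, 3, label="Y")
    x = simulate_homogeneous_poisson(1.0, 200, 5, label="X")
    cfg = EmbeddingConfig(l_X=2, l_Y=1, N_U=150)
    return build_sample_sets(x, y, (), cfg, seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
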