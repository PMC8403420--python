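import numpy as np
import pandas as pd
import pytest

from methylodyn import SimulationConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Desk-scale cohort shared across read-only tests."""
    config = SimulationConfig(n_probes=3000, markers_per_type=30, seed=11)
    return generate_cohort(config)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def tiny_beta():
    """3 probes × 2 samples with known values."""
    frame = pd.DataFrame(
        [[0.1, 0.2], [0.5, 0.4], [0.9, 1.0]],
        index=["cg01", "cg02", "cg03"], columns=["S1_BL", "S1_FU1"])
    from methylodyn import BetaMatrix
    return BetaMatrix(frame)
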