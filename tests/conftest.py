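import numpy as np
import pytest

from cytostand import SimulationConfig, simulate_experiment


@pytest.fixture(scope="session")
def tcell_experiment():
    """One small T-cell-only experiment shared across read-only tests."""
    cfg = SimulationConfig(
        n_centers=2,
        n_samples=1,
        n_replicates=1,
        events_per_file=8000,
        panels=("T-cell",),
        seed=42,
    )
    return simulate_experiment(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
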