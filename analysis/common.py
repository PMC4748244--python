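"""Shared study configuration for the numbered analysis drivers.

The drivers emulate the cryopreserved-PBMC arm of a multi-center
standardization study: nine centers stain three replicates of each of
three samples. Two panels (T-cell and B-cell) at 10,000 events per file
keep a full driver run in the minutes range; the package itself handles
all four panels and larger files.
"""

from pathlib import Path

from cytostand import SimulationConfig

RESULTS = Path(__file__).resolve().parent.parent / "results"


def study_config(seed: int = 1) -> SimulationConfig:
    return SimulationConfig(
        n_centers=9,
        n_samples=3,
        n_replicates=3,
        events_per_file=10_000,
        panels=("T-cell", "B-cell"),
        seed=seed,
    )
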