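import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for helpers.py

from spheroscreen.simgen import SimConfig


@pytest.fixture(scope="session")
def tiny_config() -> SimConfig:
    """A small assay: 2 experiments, 5 doses, 2 replicates (fast to render)."""
    return SimConfig(
        concentrations=(0.0, 0.5, 2.0, 8.0, 32.0),
        replicates_per_concentration=2,
        n_experiments=2,
        seed=11,
    )


@pytest.fixture(scope="session")
def tiny_assay(tiny_config):
    from spheroscreen.simgen import simulate_assay

    return simulate_assay(tiny_config)
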