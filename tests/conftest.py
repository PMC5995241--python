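import pytest

from mibc_subtyper.consensus_panel import ConsensusPanel
from mibc_subtyper.normalization import normalize_ncounter
from mibc_subtyper.synthetic_cohort import (
    SimulationConfig,
    default_panel,
    generate_cohort,
    truth_consensus_sets,
)


@pytest.fixture(scope="session")
def panel():
    return default_panel()


@pytest.fixture(scope="session")
def truth_consensus(panel):
    """Consensus panel built from the planted-stable signature truth."""
    return ConsensusPanel.from_labels(truth_consensus_sets(panel))


@pytest.fixture(scope="session")
def small_cohort(panel):
    return generate_cohort(SimulationConfig(n_samples=60, seed=11), panel=panel)


@pytest.fixture(scope="session")
def normalized_small(small_cohort):
    norm, _ = normalize_ncounter(small_cohort.expression)
    return norm
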