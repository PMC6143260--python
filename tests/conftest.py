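import numpy as np
import pytest

from bsaskit.panel import load_default_panel
from bsaskit.simulate import (
    CohortDesign,
    GroupSpec,
    SimulationConfig,
    simulate_cohort,
    simulate_isoforms,
)


@pytest.fixture(scope="session")
def default_panel():
    return load_default_panel()


@pytest.fixture(scope="session")
def materialized_panel(default_panel):
    """Default panel with synthesized amplicon sequences."""
    return default_panel.with_sequences(seed=7)


@pytest.fixture(scope="session")
def small_cohort(materialized_panel):
    """A 2x2-sample cohort at low coverage over the full panel."""
    design = CohortDesign(
        [GroupSpec("testes", "captive", 2), GroupSpec("ovaries", "captive", 2)]
    )
    config = SimulationConfig(design=design, coverage_per_amplicon=40, seed=3)
    return simulate_cohort(config, materialized_panel)


@pytest.fixture(scope="session")
def toy_isoforms():
    return simulate_isoforms(seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
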