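import pytest

from serodx.cohort import PANEL7_ANTIGENS, PanelDefinition
from serodx.simulate import CohortSimConfig, generate_cohort


@pytest.fixture(scope="session")
def default_config():
    return CohortSimConfig(n_cancer=300, n_control=400, n_at_risk=100, seed=123)


@pytest.fixture(scope="session")
def default_cohort(default_config):
    return generate_cohort(default_config)


@pytest.fixture(scope="session")
def true_panel7(default_config):
    cutoffs = default_config.true_cutoffs()
    return PanelDefinition(
        name="panel7",
        antigens=PANEL7_ANTIGENS,
        cutoffs={a: cutoffs[a] for a in PANEL7_ANTIGENS},
    )
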