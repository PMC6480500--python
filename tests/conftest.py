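import numpy as np
import pytest

from parage import (
    AgeCrossTab,
    AgeCurve,
    MCMCConfig,
    ModelSpec,
    SimScenario,
    fit_model,
    simulate_crosstab,
)


@pytest.fixture
def tiny_tab() -> AgeCrossTab:
    """3x4 deterministic cross-tab with hand-sized counts."""
    rng = np.random.default_rng(7)
    births = rng.integers(50, 200, size=(3, 4))
    cases = rng.binomial(births, 0.1)
    return AgeCrossTab(np.arange(20, 23), np.arange(25, 29), births, cases, "toy")


@pytest.fixture(scope="session")
def ramp_scenario() -> SimScenario:
    """Natality-like cohort: maternal risk ramp, null paternal effect, rho=0.8."""
    return SimScenario(
        total_births=2_000_000,
        maternal_curve=AgeCurve(kind="ramp", start=30, stop=45, height=2.0),
        seed=11,
    )


@pytest.fixture(scope="session")
def ramp_data(ramp_scenario):
    return simulate_crosstab(ramp_scenario)


@pytest.fixture(scope="session")
def smoke_config() -> MCMCConfig:
    """Reduced-iteration protocol for fast test fits."""
    return MCMCConfig(burn_in=300, samples=600, chains=2, seed=5)


@pytest.fixture(scope="session")
def joint_fit(ramp_data, smoke_config):
    """One joint-CAR fit on the ramp/null cohort, shared across tests."""
    tab, _ = ramp_data
    return fit_model(tab, ModelSpec.preset("model3"), smoke_config)
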