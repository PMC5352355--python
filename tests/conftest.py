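import pytest

from alkscreen.synthetic import SimConfig, build_default_panel, simulate_cohort


@pytest.fixture(scope="session")
def panel():
    return build_default_panel()


@pytest.fixture(scope="session")
def default_cohort(panel):
    """One default-size cohort (16 ALK+ / 40 negative) shared across tests."""
    cfg = SimConfig(seed=7)
    truth, probes, cts = simulate_cohort(cfg, panel)
    return cfg, truth, probes, cts
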