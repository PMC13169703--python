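import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")

from trnapanel.stats_report import PipelineConfig, analyze, inputs_from_panel
from trnapanel.synthetic_data import PanelConfig, simulate_panel


@pytest.fixture(scope="session")
def default_panel():
    """One default-condition panel (17 strains + outgroup), seed 1."""
    return simulate_panel(PanelConfig(seed=1))


@pytest.fixture(scope="session")
def default_config():
    return PipelineConfig()


@pytest.fixture(scope="session")
def default_analysis(default_panel, default_config):
    """Full pipeline result on the default panel (computed once)."""
    return analyze(inputs_from_panel(default_panel, default_config), default_config)
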