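import pytest
from hypothesis import HealthCheck, settings

from oxicopd import AnalysisConfig, SimConfig, analyze_cohort, simulate_cohort

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """A fast cohort: 1-hour nights (900 samples) instead of 7-hour nights."""
    return SimConfig(n_patients=24, night_length_h=1.0, seed=5)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return simulate_cohort(small_config)


@pytest.fixture(scope="session")
def small_analysis(small_cohort):
    records, _ = small_cohort
    return analyze_cohort(records, AnalysisConfig())
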