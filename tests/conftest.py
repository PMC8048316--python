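import pytest

from pgxcns import builtin_demo_panel
from pgxcns.simulate import (
    FrequencyProfile,
    SimulationConfig,
    clinical_case_fixtures,
    demo_frequency_profiles,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def panel():
    return builtin_demo_panel()


@pytest.fixture(scope="session")
def cases(panel):
    return clinical_case_fixtures(panel)


@pytest.fixture(scope="session")
def ceu_profile():
    return demo_frequency_profiles()["CEU"]


@pytest.fixture(scope="session")
def moderate_profile(panel):
    """All-variant profile with moderate frequencies (no monomorphism at
    small n)."""
    return FrequencyProfile(
        name="moderate", alt_freqs={rs: 0.3 for rs in panel.rsids}
    )


@pytest.fixture(scope="session")
def small_cohort(panel, moderate_profile):
    return simulate_cohort(
        SimulationConfig(n_samples=60, profile=moderate_profile, seed=11), panel
    )
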