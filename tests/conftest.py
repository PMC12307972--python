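import pytest

from cyclewealth import VillageSpec, assemble_analysis_table, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Two-wave cohort of 4 small villages (shared across tests)."""
    return generate_cohort(4, VillageSpec(n_households=10), seed=11)


@pytest.fixture(scope="session")
def small_table(small_cohort):
    """Wide analysis table for the small cohort, k = 3 only."""
    return assemble_analysis_table(small_cohort, K=3, use_mca=False)
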