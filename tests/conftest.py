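import pytest

from fibergxe import SimulationConfig, default_panel, reference_genotype_counts, simulate_cohort


@pytest.fixture(scope="session")
def panel():
    return default_panel()


@pytest.fixture(scope="session")
def ref_counts():
    return reference_genotype_counts()


@pytest.fixture(scope="session")
def small_cohort(panel):
    """A 150-pair matched cohort with a modest genotype and fiber effect."""
    config = SimulationConfig(
        n_pairs=150, population_size=2500, beta_interaction=0.0, seed=42
    )
    cohort, truth = simulate_cohort(config, panel)
    return cohort
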