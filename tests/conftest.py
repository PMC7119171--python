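import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from aimpanel import (
    MarkerFrequencyTable,
    PopulationPanel,
    SimulationConfig,
    simulate_ancestral_frequencies,
    simulate_genotypes,
)


@pytest.fixture
def trio_panel():
    """Three continental-style populations, equal weighting."""
    return PopulationPanel(("CEU", "CHB", "YRI"))


@pytest.fixture
def pair_panel():
    return PopulationPanel(("A", "B"))


@pytest.fixture
def worked_example_table(trio_panel):
    """Two-marker table: one non-informative, one strongly differentiated."""
    return MarkerFrequencyTable(
        panel=trio_panel,
        ids=["rs7289657", "rs2294368"],
        freqs=np.array([[0.4, 0.4, 0.4], [0.79, 0.17, 0.99]]),
        chromosomes=["22", "22"],
        positions=np.array([16_050_000.0, 39_665_000.0]),
        ref_alleles=["C", "T"],
        alt_alleles=["T", "C"],
    )


@pytest.fixture(scope="session")
def diverse_cohort():
    """Seeded three-population cohort at continental-scale divergence."""
    cfg = SimulationConfig(k=3, m=300, fst=0.15, samples_per_pop=60, seed=7)
    freqs = simulate_ancestral_frequencies(cfg)
    genotypes = simulate_genotypes(freqs, cfg.samples_per_pop, cfg.seed)
    return cfg, freqs, genotypes
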