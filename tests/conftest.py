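import pytest

from phosnet.simulate import SimulationConfig, simulate_all


@pytest.fixture(scope="session")
def default_study():
    """One synthetic study at the default design (3v3, 200 sites, 4-fold)."""
    return simulate_all(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(
        seed=5,
        n_proteins=20,
        n_sites=40,
        baseline_rate=5.0,
        n_kinases=4,
        substrates_per_kinase=10,
        n_active_kinases=2,
        ppi_modules=((5, 0.9),),
        n_terms=6,
        genes_per_term=6,
    )
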