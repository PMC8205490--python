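import warnings

import pytest

import aragsl as ag


@pytest.fixture(scope="session")
def study_cohort():
    """A mid-size cohort at study-like conditions, shared across tests."""
    cfg = ag.SimulationConfig(n_accessions=200, seed=42)
    truth = ag.simulate_accessions(cfg)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        meta, truth = ag.simulate_environment(truth, cfg)
    measurements = ag.simulate_profiles(truth, cfg)
    return cfg, truth, meta, measurements


@pytest.fixture(scope="session")
def small_alignment():
    """Clade-structured alignment for a 60-accession cohort."""
    cfg = ag.SimulationConfig(n_accessions=60, seed=7)
    truth = ag.simulate_accessions(cfg)
    return truth, ag.simulate_sequences(truth, cfg)


@pytest.fixture
def registry():
    return ag.default_registry()
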