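import pytest

from frost.synthetic import SyntheticScenario


@pytest.fixture
def noise_free_scenario() -> SyntheticScenario:
    """Deterministic generator conditions: no sensor or assay noise."""
    return SyntheticScenario(trace_sigma_K=0.0, fv_fm_sigma=0.0)


@pytest.fixture
def small_scenario() -> SyntheticScenario:
    """A reduced species pool for end-to-end smoke tests."""
    return SyntheticScenario(n_species=6, n_plots=10, replicates=3)
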