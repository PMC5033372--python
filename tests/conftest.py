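import pytest

import selenoqpcr as sq


@pytest.fixture(scope="session")
def panel():
    return sq.default_panel()


@pytest.fixture(scope="session")
def fixture_frame(panel):
    return sq.load_results_fixture(panel=panel)


@pytest.fixture(scope="session")
def abundance_frame(panel):
    return sq.load_abundance_fixture(panel=panel)


@pytest.fixture(scope="session")
def noise_free_ct(panel, fixture_frame, abundance_frame):
    """CT table simulated without noise from the transcribed outcomes."""
    sc = sq.scenario_from_fixture(fixture_frame, abundance_frame, panel,
                                  mode="combined", ct_noise_sd=0.0)
    return sq.simulate_ct(sc)


@pytest.fixture(scope="session")
def noise_free_results(noise_free_ct, panel):
    config = sq.RunConfig(ct_noise_sd=0.0)
    results = sq.run_two_phase(noise_free_ct, panel, config)
    return sq.results_to_frame(results, config)
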