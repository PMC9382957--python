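import pytest

from emovocab import coding, default_design, simulate_responses
from emovocab.simulate import SimulationParams


@pytest.fixture(scope="session")
def design():
    return default_design()


@pytest.fixture(scope="session")
def lexicon(design):
    return design.lexicon


@pytest.fixture(scope="session")
def responses(design):
    """One default synthetic study run (seed 1)."""
    return simulate_responses(design, SimulationParams(seed=1))


@pytest.fixture(scope="session")
def coded(design, responses):
    return coding.code_dataset(responses, design.lexicon, design=design)


@pytest.fixture(scope="session")
def noise_free(design):
    """The deterministic-knowledge limit: everyone knows every word and
    always answers."""
    params = SimulationParams(
        vocab_curve={g: 1.0 for g in design.age_groups},
        overgeneralize_basic=0.0,
        unspecific_rate=0.0,
        dont_know_rate={g: 0.0 for g in design.age_groups},
        valence_error_rate=0.0,
        seed=7,
    )
    return simulate_responses(design, params)
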