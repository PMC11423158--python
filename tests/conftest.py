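import pytest

from aptatrigger.design import assemble_apta_trigger
from aptatrigger.parts import generate_toy_start_set, load_aptamer


@pytest.fixture(scope="session")
def theophylline():
    return load_aptamer("theophylline")


@pytest.fixture(scope="session")
def start_set():
    """Four matched toy (switch, trigger pair, aptamer) triples, seed 7."""
    return generate_toy_start_set(4, 7)


@pytest.fixture(scope="session")
def toy_designs(start_set):
    """Assembled apta-triggers for the toy set, one per switch."""
    return [
        assemble_apta_trigger(pair, apt, switch_id=chr(65 + i))
        for i, (_, pair, apt) in enumerate(start_set)
    ]
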