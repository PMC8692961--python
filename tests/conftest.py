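import pytest

from chemfsa.automata import build_cycle_fsa, build_sqrt_fsa
from chemfsa.compiler import RateConfig, compile_for_consumable_inputs


@pytest.fixture(scope="session")
def sqrt_fsa():
    return build_sqrt_fsa()


@pytest.fixture(scope="session")
def three_cycle_fsa():
    return build_cycle_fsa(3)


@pytest.fixture()
def three_cycle_crn(three_cycle_fsa):
    return compile_for_consumable_inputs(three_cycle_fsa, RateConfig(), 100)
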