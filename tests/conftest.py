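import pytest
from hypothesis import settings

from pddikit import fixtures as fx

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")
from pddikit.value_sets import ValueSetRegistry


@pytest.fixture()
def registry() -> ValueSetRegistry:
    return fx.demo_registry()


@pytest.fixture()
def warfarin_nsaid():
    return fx.warfarin_nsaid_artifact()


@pytest.fixture()
def tki_ppi():
    return fx.tki_ppi_artifact()


@pytest.fixture()
def exemplars():
    return fx.exemplar_registry()
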