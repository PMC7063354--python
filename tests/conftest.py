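import pytest
from hypothesis import HealthCheck, settings

from pepmine.cleavage import bundled_gi_rules, bundled_plant_rules
from pepmine.dictionary import BioactiveDictionary, PeptideEntry, bundled_dictionary

settings.register_profile(
    "deterministic",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def gi_rules():
    return bundled_gi_rules()


@pytest.fixture(scope="session")
def plant_rules():
    return bundled_plant_rules()


@pytest.fixture(scope="session")
def demo_dict():
    return bundled_dictionary()


@pytest.fixture()
def tiny_dict():
    return BioactiveDictionary(
        [
            PeptideEntry("PF", "DPP-IV inhibitor"),
            PeptideEntry("IR", "ACE inhibitor"),
        ]
    )
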