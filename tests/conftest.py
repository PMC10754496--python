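import pytest

from dendrosynergy import (DensityRuleSet, PassiveParams, System,
                           generate_synthetic_morphology)


@pytest.fixture(scope="session")
def morphology():
    return generate_synthetic_morphology()


@pytest.fixture(scope="session")
def passive():
    return PassiveParams()


@pytest.fixture(scope="session")
def rules():
    return DensityRuleSet()


@pytest.fixture(scope="session")
def bare_system(morphology, passive, rules):
    """The default synthetic cell with no synapses bound."""
    return System(morphology, passive, rules, [])


from hypothesis import settings as _hyp_settings

_hyp_settings.register_profile("stable", derandomize=True)
_hyp_settings.load_profile("stable")
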