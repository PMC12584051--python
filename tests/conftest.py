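import pytest

from aibilling import CostBenefitInputs, packaged_registry
from aibilling.schedule import get_regime


@pytest.fixture(scope="session")
def registry():
    """The packaged five-code AI billing table."""
    return packaged_registry()


@pytest.fixture(scope="session")
def ebm_simplified():
    return get_regime("ebm-simplified")


@pytest.fixture(scope="session")
def goa():
    return get_regime("goa")


@pytest.fixture
def baseline_inputs():
    """The published illustrative cost-benefit scenario (all defaults)."""
    return CostBenefitInputs()
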