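import pytest

from oncocap import CapacityNorms, MergeRule, merge_available_categories
from oncocap import io as ocio


@pytest.fixture(scope="session")
def up_incidence():
    return ocio.up_incidence()


@pytest.fixture(scope="session")
def fractions():
    return ocio.default_fractions()


@pytest.fixture(scope="session")
def norms():
    return CapacityNorms()


@pytest.fixture(scope="session")
def up_overrides():
    return ocio.up_overrides()


@pytest.fixture(scope="session")
def up_inventory():
    """State inventory with gastro-surgeons folded into surgical oncologists."""
    return merge_available_categories(
        ocio.up_availability(),
        [MergeRule(sources=["gastro_surgeons"], into="surgical_oncologists")],
    )
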