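import pytest
from hypothesis import HealthCheck, settings

import asdscreen as asd

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def fedors_table():
    return asd.load_bundled_table("fedors")


@pytest.fixture(scope="session")
def vk_table():
    return asd.load_bundled_table("van_krevelen")


@pytest.fixture(scope="session")
def compounds():
    return asd.load_all_compounds()


@pytest.fixture(scope="session")
def printed_parameters():
    """Published per-compound solubility parameters / molar volumes."""
    return asd.load_printed_table("table3").set_index("abbr")


@pytest.fixture(scope="session")
def printed_screening():
    """Published per-pair screening values (differences, chi, distances)."""
    return asd.load_printed_table("table4")


@pytest.fixture(scope="session")
def printed_rankings():
    """Published top-3 polymer rankings with agreement scores."""
    return asd.load_printed_rankings()
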