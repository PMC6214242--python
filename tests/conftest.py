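import logging

import pytest

from sitegraphs import LandscapeConfig, generate_landscape

logging.getLogger("sitegraphs").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_bundle():
    """A compact landscape shared by read-only tests."""
    return generate_landscape(LandscapeConfig(n_sites=40, seed=7))


@pytest.fixture(scope="session")
def full_bundle():
    """A case-study-sized landscape (104 base sites)."""
    return generate_landscape(LandscapeConfig(n_sites=104, seed=11))
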