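import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("default", derandomize=True, max_examples=100)
settings.load_profile("default")

from ppiscreen.fixtures import FixtureSpec, make_bound, make_confidence, make_dimer


@pytest.fixture
def clean_spec():
    """A contact-rich, clash-free toy dimer with constant cross-chain PAE."""
    return FixtureSpec(separation=7.0, pae_interface=5.0, pae_intra=2.0)


@pytest.fixture
def clean_dimer(clean_spec):
    return make_dimer(clean_spec)


@pytest.fixture
def clean_bound(clean_spec):
    return make_bound(clean_spec)


@pytest.fixture
def separated_bound():
    return make_bound(FixtureSpec(separation=20.0))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
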