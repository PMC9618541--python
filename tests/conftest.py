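import numpy as np
import pytest

from slf_maturation import synthetic_data as sd


@pytest.fixture(scope="session")
def phantom():
    """Default 48^3 phantom layout and its label volume."""
    return sd.make_phantom()


@pytest.fixture(scope="session")
def adult_mix(phantom):
    """Default adult bundle mix: tractogram plus per-streamline provenance."""
    layout, _ = phantom
    return sd.simulate_tractogram(layout, sd.default_bundle_mix("adult"), seed=7)


@pytest.fixture(scope="session")
def dhcp():
    return sd.dhcp_scheme()


@pytest.fixture()
def rng():
    return np.random.default_rng(20260923)
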