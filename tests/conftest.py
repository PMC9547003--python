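import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from kymotrap.structures import EWLCParams
from kymotrap.simulate import RuptureSpec, SyntheticSceneConfig

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    # read-only fixtures (frozen dataclasses / parameter sets) are safe
    # to share across generated examples
    suppress_health_check=[HealthCheck.function_scoped_fixture],
)
settings.load_profile("ci")


@pytest.fixture
def dna_params():
    """eWLC parameters of the 15 kbp junction-containing tether."""
    return EWLCParams(Lp=45.0, Lc=4902.0, S=1200.0)


@pytest.fixture
def rupture_spec():
    """Deterministic junction rupture: 23 pN unfold, 14 pN refold, 9.5 nm."""
    return RuptureSpec(23.0, 0.0, 14.0, 0.0, 9.5, 0.0)


@pytest.fixture
def scene():
    """Default synthetic kymograph scene (60 s at 10 Hz, 15 kbp tether)."""
    return SyntheticSceneConfig(seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
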