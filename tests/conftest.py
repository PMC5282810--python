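import warnings

import numpy as np
import pytest

import krigdoe as kd
from krigdoe import presets
from krigdoe.synthetic_data import default_surface


@pytest.fixture
def base_space():
    """The packaged nine-variable screening factor space."""
    return kd.reduce_components(presets.COMPONENT_TABLE, bounds=presets.ROUND12_BOUNDS)


@pytest.fixture
def core_space(base_space):
    """The four refinement factors with round-3/4 bounds."""
    return base_space.subset(presets.ROUND34_FACTORS, bounds=presets.ROUND34_BOUNDS,
                             require_reference_inside=False)


@pytest.fixture
def surface():
    return default_surface()


@pytest.fixture(scope="session")
def campaign_seed1():
    """One full noisy campaign, shared across tests (expensive)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return kd.run_campaign(seed=1, surface=default_surface(seed=1))


@pytest.fixture(scope="session")
def noiseless_campaign():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return kd.run_campaign(seed=1, surface=default_surface(noise_cv=0.0))
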