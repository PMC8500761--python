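import numpy as np
import pytest

from wristseg import PipelineConfig, default_wrist_spec, generate_phantom
from wristseg.phantom import noiseless_spec


@pytest.fixture(scope="session")
def default_phantom():
    """One noisy default wrist phantom, shared across tests."""
    return generate_phantom(default_wrist_spec(seed=0))


@pytest.fixture(scope="session")
def clean_phantom():
    """The same phantom with noise and bias disabled."""
    return generate_phantom(noiseless_spec(default_wrist_spec(seed=0)))


@pytest.fixture(scope="session")
def two_region_image():
    """Noise-free 64x64 image with a single bright disk on background."""
    from wristseg import PhantomSpec, Region

    spec = PhantomSpec(
        width=64,
        height=64,
        regions=(Region("ellipse", center=(32, 32), axes=(14, 18), intensity=0.8),),
        lesion_index=0,
        background=0.2,
    )
    return generate_phantom(spec)


@pytest.fixture
def config():
    return PipelineConfig(seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
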