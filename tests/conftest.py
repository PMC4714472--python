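import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ws2pet import PhantomSpec, Volume, make_phantom
from ws2pet.synthetic import gaussian_blob_field

settings.register_profile(
    "ci",
    max_examples=25,
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_phantom():
    """32^3 phantom at 2 mm with focal blobs and mild noise."""
    return make_phantom(PhantomSpec(
        shape=(32, 32, 32), spacing=(2.0, 2.0, 2.0),
        n_blobs=4, blob_amplitude=1.0, noise_sd=0.05, seed=11,
    ))


@pytest.fixture(scope="session")
def clean_phantom():
    """Noise-free 32^3 phantom with blobs (deterministic oracle target)."""
    return make_phantom(PhantomSpec(
        shape=(32, 32, 32), spacing=(2.0, 2.0, 2.0),
        n_blobs=4, blob_amplitude=1.0, noise_sd=0.0, seed=3,
    ))


@pytest.fixture(scope="session")
def blob_volume():
    """12^3 blob image at 1 mm spacing, small enough for exhaustive wS2."""
    rng = np.random.default_rng(0)
    centers = rng.integers(2, 10, size=(3, 3))
    data = 1.0 + gaussian_blob_field((12, 12, 12), (1.0, 1.0, 1.0),
                                     centers, 1.5, 2.0)
    vol = Volume(data, np.eye(4))
    mask = np.ones((12, 12, 12), dtype=bool)
    return vol, mask
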