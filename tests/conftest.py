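import numpy as np
import pytest
from hypothesis import settings

from coralskel.phantom import PhantomSpec, generate_polyp_phantom

settings.register_profile("ci", max_examples=50, deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_spec():
    """Compact polyp phantom used across modules (fast to generate)."""
    return PhantomSpec(
        grid_shape=(64, 64, 60),
        voxel_size=2.2,
        wall_radius=55.0,
        septum_width_profile=12.0,
        septum_length_profile=36.0,
        rad_radius=3.5,
        rad_onset_fraction=0.05,
        noise_sd=0.0,
        seed=123,
    )


@pytest.fixture(scope="session")
def small_phantom(small_spec):
    return generate_polyp_phantom(small_spec)


@pytest.fixture(scope="session")
def noisy_phantom(small_spec):
    import dataclasses

    return generate_polyp_phantom(dataclasses.replace(small_spec, noise_sd=1.0))


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
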