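import numpy as np
import pytest

from endostitch.synthetic_fixtures import FixtureSpec, generate_pair


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def easy_pair():
    """One deterministic synthetic frame pair with modest motion."""
    return generate_pair(
        FixtureSpec(
            size=(256, 256),
            rotation=2.0,
            scale=1.0,
            translation=(20.0, 5.0),
            noise_sigma=0.005,
            illumination=0.05,
            seed=7,
        )
    )


@pytest.fixture(scope="session")
def textured_image():
    """A 256x256 band-limited texture with blobs (no second frame)."""
    pair = generate_pair(FixtureSpec(size=(256, 256), noise_sigma=0.0, seed=11))
    return pair.frame_a
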