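import numpy as np
import pytest

import mtquant as mq


@pytest.fixture(scope="session")
def small_sliding_params():
    """A reduced-size sliding simulation for fast unit tests."""
    return mq.SlidingSimParams(
        image_shape=(96, 96), zone_center=(48.0, 48.0), zone_radius=20.0,
        n_filaments=8, filament_length_range=(4.0, 6.0), n_frames=8,
        velocity=0.3, seed=7,
    )


@pytest.fixture(scope="session")
def small_sliding_movie(small_sliding_params):
    return mq.simulate_sliding_movie(small_sliding_params)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
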