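import numpy as np
import pytest

import gcflow as g


@pytest.fixture
def small_scene():
    """One-neurite scene, cheap to render, with all channels active."""
    return g.SceneConfig(
        image_shape=(60, 100), duration_s=60.0,
        neurites=[g.NeuriteSpec(base_xy=(10.0, 30.0), tip_xy=(80.0, 30.0))],
        rng_seed=7)


@pytest.fixture
def noiseless_track_kymo():
    """Single retrograde track, slope -1 px/frame, no noise."""
    kymo, endpoints = g.simulate_kymograph(
        -1.0, 1, (100, 151), line_intensity=50.0, noise_sd=0.0,
        rng_seed=0, offsets=[120.0])
    return kymo, endpoints
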