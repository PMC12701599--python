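"""Shared fixtures: small synthetic scene sets and a trained tiny network.

Scene sets are generated at desk scale (96 px canvas, 3 mm seeds, 2-3 px
roots) so that a full training run stays in seconds; session scope keeps
the one trained network shared across the tests that need it.
"""

import numpy as np
import pytest

from rootarm.backbone import TinySegNet
from rootarm.synthgerm import generate_dataset
from rootarm.train import TrainSettings, train_segmentation

DESK_SCENE_KWARGS = dict(
    n_seeds=3,
    canvas=(96, 96),
    root_length_range_mm=(2.0, 6.0),
    root_width_px=(2, 3),
    seed_diameter_mm=3.0,
)


@pytest.fixture(scope="session")
def small_scenes():
    return generate_dataset(10, rng_seed=11, **DESK_SCENE_KWARGS)


@pytest.fixture(scope="session")
def holdout_scenes():
    return generate_dataset(10, rng_seed=99, **DESK_SCENE_KWARGS)


@pytest.fixture(scope="session")
def trained_net(small_scenes):
    net = TinySegNet(rng_seed=0)
    train_segmentation(net, small_scenes, TrainSettings(epochs=30, rng_seed=0))
    return net


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
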