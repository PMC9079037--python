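import numpy as np
import pytest

from neotherm.keypoints import KEYPOINT_NAMES, KeypointSet
from neotherm.phantom import PhantomConfig, generate_phantom_pair
from neotherm.registration import RegistrationMap

SMALL_RGB = (480, 300)
SMALL_IRT = (256, 192)


def small_phantom_config(**overrides) -> PhantomConfig:
    """Quarter-scale phantom used throughout the unit tests (the geometry,
    temperatures and map are scaled consistently with the full-size
    defaults)."""
    kwargs = dict(
        rgb_size=SMALL_RGB,
        irt_size=SMALL_IRT,
        true_map=RegistrationMap.from_params(
            tx=10.0, ty=6.0, sx=0.58, sy=0.60, theta_deg=3.0,
            crop_x=37.0, crop_y=25.0),
        figure_scale_px=250.0,
        seed=0,
    )
    kwargs.update(overrides)
    return PhantomConfig(**kwargs)


@pytest.fixture(scope="session")
def small_pair_truth():
    return generate_phantom_pair(small_phantom_config())


@pytest.fixture(scope="session")
def noiseless_pair_truth():
    cfg = small_phantom_config(noise_sd_irt=0.0, noise_sd_rgb=0.0)
    return generate_phantom_pair(cfg)


def full_keypoint_set(rng: np.random.Generator, frame=(256, 192),
                      area=5000.0) -> KeypointSet:
    """A fully-visible random keypoint set inside a frame."""
    w, h = frame
    x = rng.uniform(0.1 * w, 0.9 * w, len(KEYPOINT_NAMES))
    y = rng.uniform(0.1 * h, 0.9 * h, len(KEYPOINT_NAMES))
    return KeypointSet(x=x, y=y, visibility=np.full(len(KEYPOINT_NAMES), 2),
                       scale_area=area)
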