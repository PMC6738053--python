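import numpy as np
import pytest

from hypoxvasc.images import ChannelImage, RegionMask
from hypoxvasc.synthetic_slides import SlideSimParams, generate_slide


@pytest.fixture(scope="session")
def small_slide():
    """A small noiseless slide whose segmentation is exactly recoverable."""
    params = SlideSimParams(
        image_shape=(160, 160),
        tumour_mask_fraction=0.7,
        true_caix_fraction=0.08,
        n_vessels=8,
        noise_speckle_rate=0.0,
        noise_sigma=0.0,
        seed=42,
    )
    return params, generate_slide(params)


@pytest.fixture
def full_mask():
    return lambda shape: RegionMask(np.ones(shape, dtype=bool))


@pytest.fixture
def as_channel():
    return lambda arr, label="hypoxia": ChannelImage(
        np.asarray(arr, dtype=float), 1.0, label
    )
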