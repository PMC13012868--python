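import numpy as np
import pytest

from dropsieve.synthetic import DropletSpec, FieldSpec, render_field, sample_droplets


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def droplet_field():
    """A clean 128x128 field with 8 known droplets on a flat background."""
    r = np.random.default_rng(0)
    droplets = sample_droplets(r, (128, 128), 8, diameter=12, peak_intensity=120)
    spec = FieldSpec(shape=(128, 128), droplets=droplets, background_level=20.0, noise_sd=4.0, seed=1)
    image, truth = render_field(spec)
    return spec, image, truth


def make_field(seed, shape=(96, 96), n=6, diameter=12.0, peak=120.0, noise_sd=0.0, background=0.0, aspect_ratio=1.0):
    r = np.random.default_rng(seed)
    droplets = sample_droplets(r, shape, n, diameter=diameter, peak_intensity=peak, aspect_ratio=aspect_ratio)
    spec = FieldSpec(shape=shape, droplets=droplets, background_level=background, noise_sd=noise_sd, seed=seed)
    image, truth = render_field(spec)
    return spec, image, truth
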