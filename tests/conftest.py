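import numpy as np
import pytest

from lavs.data import SamplePair
from lavs.model import NetConfig, SegModel, TransformerConfig
from lavs.synthetic import VesselTreeParams, generate_vessel_mask, render_fundus


def tiny_transformer(**kw):
    base = dict(n_layers=2, n_heads=4, patch_size=4, pos_grid=4)
    base.update(kw)
    return TransformerConfig(**base)


def tiny_net(variant="transunet_sld", **kw):
    base = dict(variant=variant, channels=(8, 16, 32),
                transformer=tiny_transformer(), landmark_channels=8, seed=0)
    base.update(kw)
    return NetConfig(**base)


def synth_pair(seed, size=64, contrast=0.6, noise_sd=0.02):
    params = VesselTreeParams(seed=seed, canvas_size=(size, size), n_roots=2,
                              max_depth=4, root_width=2.5)
    mask = generate_vessel_mask(params)
    image = render_fundus(mask, seed=seed, contrast=contrast, noise_sd=noise_sd)
    return SamplePair(image=image, mask=mask, id=f"synth{seed}")


@pytest.fixture(scope="session")
def tiny_model():
    return SegModel(tiny_net())


@pytest.fixture(scope="session")
def pair64():
    return synth_pair(0)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
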