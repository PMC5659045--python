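import numpy as np
import pytest

from retinascreen.core_io import PipelineConfig, green_channel
from retinascreen.phantom import PhantomSpec, generate


@pytest.fixture(scope="session")
def phantom1():
    """One DRIVE-sized phantom with full ground truth."""
    return generate(PhantomSpec(seed=1))


@pytest.fixture(scope="session")
def phantom_green(phantom1):
    img, _gt = phantom1
    return green_channel(img)


@pytest.fixture(scope="session")
def cfg():
    return PipelineConfig()


@pytest.fixture(scope="session")
def enhanced1(phantom1, phantom_green, cfg):
    from retinascreen.preprocess import enhance
    img, _ = phantom1
    return enhance(phantom_green, cfg, fov=img.field_of_view_mask)


@pytest.fixture(scope="session")
def vessels1(phantom1, phantom_green, enhanced1, cfg):
    from retinascreen.vessels import segment_vessels
    img, _ = phantom1
    return segment_vessels(phantom_green, enhanced1, img.field_of_view_mask, cfg)


@pytest.fixture(scope="session")
def models():
    """Lesion classifiers trained on a small phantom batch."""
    from retinascreen.pipeline import default_models
    return default_models(seed=0, n_images=8)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
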